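"""Preprocessing chain: detrend/filter → bad channels → interpolation →
average reference → epoching/baseline → artifact rejection → CSD.

All window boundaries are half-open ``[start, end)`` in ms. Artifact
rejection is run independently for cue-locked and evidence-locked
epochs; response-locked epochs are cut from the surviving
evidence-locked data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import signal as sps

from .containers import BASELINE_WINDOWS, EEGEpoch, EPOCH_SPANS, Montage

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    lowpass_hz: float = 40.0
    filter_numtaps: int = 257           # odd -> symmetric, zero-phase FIR
    veog_reject_uv: float = 250.0
    scalp_reject_uv: float = 100.0
    bad_channel_z: float = 3.5
    csd_spline_order: int = 4           # Perrin m parameter
    csd_lambda: float = 1e-5
    spline_n_legendre: int = 50
    baseline_windows: dict = field(default_factory=lambda: dict(BASELINE_WINDOWS))
    epoch_spans: dict = field(default_factory=lambda: dict(EPOCH_SPANS))


# ---------------------------------------------------------------------------
# filtering

def _lowpass_kernel(cfg: PreprocConfig, fs: float) -> np.ndarray:
    # Hamming FIR, -6 dB at the cutoff
    return sps.firwin(cfg.filter_numtaps, cfg.lowpass_hz, fs=fs, window="hamming")


def detrend_filter(epoch: EEGEpoch, cfg: PreprocConfig = None) -> EEGEpoch:
    """Remove each channel's linear trend, then zero-phase low-pass.

    The filter is a symmetric (linear-phase) Hamming-window FIR applied
    with 'same'-mode convolution, so there is no group delay to
    compensate.
    """
    cfg = cfg or PreprocConfig()
    data = sps.detrend(epoch.data, axis=1, type="linear")
    h = _lowpass_kernel(cfg, epoch.fs_hz)
    pad = len(h) // 2
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="reflect")
    out = sps.fftconvolve(padded, h[None, :], mode="same", axes=1)[:, pad:-pad]
    return EEGEpoch(out, epoch.t0_ms, epoch.alignment, epoch.montage,
                    epoch.trial_uid, epoch.fs_hz)


# ---------------------------------------------------------------------------
# bad channels

def detect_bad_channels(
    data: np.ndarray,
    montage: Montage,
    cfg: PreprocConfig = None,
) -> set[str]:
    """Channel-variance screen: robust z on log variance, two-sided.

    ``data`` is channels x samples (or trials x channels x samples,
    pooled over trials). Channels whose log-variance robust z-score
    exceeds the threshold in either direction are flagged — dead (flat)
    channels on the low side, noisy channels on the high side.
    """
    cfg = cfg or PreprocConfig()
    if data.ndim == 3:
        data = np.concatenate(list(data), axis=1)
    scalp = data[: montage.n_scalp]
    if scalp.shape[0] < 8:
        raise ValueError("need at least 8 scalp channels for the variance screen")
    var = scalp.var(axis=1)
    flagged = set()
    flat = var <= np.finfo(float).tiny
    logv = np.log(np.where(flat, np.nan, var))
    med = np.nanmedian(logv)
    mad = np.nanmedian(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.nanstd(logv)
    for i, name in enumerate(montage.names):
        if flat[i]:
            flagged.add(name)
        elif scale > 0 and abs(logv[i] - med) / scale > cfg.bad_channel_z:
            flagged.add(name)
    if len(flagged) > 0.2 * montage.n_scalp:
        logger.warning("more than 20%% of channels flagged bad: %s", sorted(flagged))
    return flagged


# ---------------------------------------------------------------------------
# spherical splines (Perrin et al., 1989)

def _legendre_series(cos_mat: np.ndarray, m: int, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """g(cos) and h(cos) Legendre sums used by interpolation and CSD."""
    n = np.arange(1, n_terms + 1, dtype=float)
    g_coef = np.zeros(n_terms + 1)
    h_coef = np.zeros(n_terms + 1)
    g_coef[1:] = (2 * n + 1) / (n * (n + 1)) ** m
    h_coef[1:] = (2 * n + 1) / (n * (n + 1)) ** (m - 1)
    g = npleg.legval(cos_mat, g_coef) / (4 * np.pi)
    h = npleg.legval(cos_mat, h_coef) / (4 * np.pi)
    return g, h


def _spline_system(pos: np.ndarray, m: int, lam: float, n_terms: int) -> np.ndarray:
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    g, _ = _legendre_series(cosang, m, n_terms)
    n = len(pos)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = g + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    return A


def interpolate_channels(
    epoch: EEGEpoch,
    bad: set[str],
    cfg: PreprocConfig = None,
) -> EEGEpoch:
    """Replace bad scalp channels by their spherical-spline estimate."""
    cfg = cfg or PreprocConfig()
    if not bad:
        return epoch
    montage = epoch.montage
    unknown = bad - set(montage.names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    if len(bad) > 0.5 * montage.n_scalp:
        raise ValueError("more than half the scalp channels are bad")

    good_idx = [i for i, nm in enumerate(montage.names) if nm not in bad]
    bad_idx = [i for i, nm in enumerate(montage.names) if nm in bad]
    pos_good = montage.positions[good_idx]
    pos_bad = montage.positions[bad_idx]

    A = _spline_system(pos_good, cfg.csd_spline_order, cfg.csd_lambda,
                       cfg.spline_n_legendre)
    rhs = np.zeros((len(good_idx) + 1, epoch.n_samples))
    rhs[:-1] = epoch.data[good_idx]
    coef = np.linalg.solve(A, rhs)  # spline weights + constant term

    cos_bg = np.clip(pos_bad @ pos_good.T, -1.0, 1.0)
    g_bg, _ = _legendre_series(cos_bg, cfg.csd_spline_order, cfg.spline_n_legendre)
    est = g_bg @ coef[:-1] + coef[-1]

    out = epoch.data.copy()
    out[bad_idx] = est
    return EEGEpoch(out, epoch.t0_ms, epoch.alignment, montage,
                    epoch.trial_uid, epoch.fs_hz)


def csd_transform(epoch: EEGEpoch, cfg: PreprocConfig = None) -> EEGEpoch:
    """Surface-Laplacian (current source density) estimate.

    Spherical-spline CSD: fit the spline to the scalp potentials and
    evaluate the surface Laplacian via the h() series. Output units are
    µV/m² up to the (unit) head-radius scale; VEOG channels pass through
    untouched. The transform is linear and maps spatially uniform fields
    to zero.
    """
    cfg = cfg or PreprocConfig()
    montage = epoch.montage
    pos = montage.positions
    A = _spline_system(pos, cfg.csd_spline_order, cfg.csd_lambda,
                       cfg.spline_n_legendre)
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    _, h = _legendre_series(cosang, cfg.csd_spline_order, cfg.spline_n_legendre)

    n = montage.n_scalp
    rhs = np.zeros((n + 1, epoch.n_samples))
    rhs[:-1] = epoch.scalp_data()
    coef = np.linalg.solve(A, rhs)
    out = epoch.data.copy()
    out[:n] = h @ coef[:-1]
    return EEGEpoch(out, epoch.t0_ms, epoch.alignment, montage,
                    epoch.trial_uid, epoch.fs_hz)


def csd_matrix(montage: Montage, cfg: PreprocConfig = None) -> np.ndarray:
    """The CSD transform as an explicit (n_scalp x n_scalp) matrix."""
    cfg = cfg or PreprocConfig()
    n = montage.n_scalp
    A = _spline_system(montage.positions, cfg.csd_spline_order, cfg.csd_lambda,
                       cfg.spline_n_legendre)
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    _, h = _legendre_series(cosang, cfg.csd_spline_order, cfg.spline_n_legendre)
    Ainv = np.linalg.inv(A)
    return h @ Ainv[:-1, :n]


# ---------------------------------------------------------------------------
# referencing / epoching / rejection

def rereference_average(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract the scalp-channel mean per sample (VEOG excluded)."""
    out = epoch.data.copy()
    n = epoch.montage.n_scalp
    out[:n] -= out[:n].mean(axis=0, keepdims=True)
    return EEGEpoch(out, epoch.t0_ms, epoch.alignment, epoch.montage,
                    epoch.trial_uid, epoch.fs_hz)


def epoch_and_baseline(
    record: EEGEpoch,
    epoch_type: str,
    cfg: PreprocConfig = None,
) -> EEGEpoch:
    """Cut one epoch type out of a continuous trial record and baseline it.

    Spans (relative to evidence onset): cue-locked −1700:500, evidence-
    locked −400:2000; the per-type baseline-window mean is subtracted per
    channel. Raises if the record does not cover the span.
    """
    cfg = cfg or PreprocConfig()
    if epoch_type not in ("cue", "evidence"):
        raise ValueError("epoch_type must be 'cue' or 'evidence'")
    start, stop = cfg.epoch_spans[epoch_type]
    ep = record.crop(start, stop, alignment=epoch_type)
    # the evidence-locked baseline window (-600:-400) precedes the epoch
    # span, so the baseline mean is taken from the source record
    b0, b1 = cfg.baseline_windows[epoch_type]
    i0, i1 = record.sample_index(b0), record.sample_index(b1)
    if not 0 <= i0 < i1 <= record.n_samples:
        raise ValueError("baseline window outside the recorded span")
    ep.data -= record.data[:, i0:i1].mean(axis=1, keepdims=True)
    return ep


def cut_response_locked(
    epoch: EEGEpoch,
    rt_ms: float,
    cfg: PreprocConfig = None,
) -> Optional[EEGEpoch]:
    """Cut the −600:400 ms response-locked epoch from evidence-locked data.

    Returns None (trial dropped, logged) when the response is too close
    to the epoch edge for the span to fit.
    """
    cfg = cfg or PreprocConfig()
    start, stop = cfg.epoch_spans["response"]
    try:
        return epoch.crop(rt_ms + start, rt_ms + stop, alignment="response",
                          new_zero_ms=rt_ms)
    except ValueError:
        logger.info("trial %s dropped: response at %.0f ms too near epoch edge",
                    epoch.trial_uid, rt_ms)
        return None


def reject_artifacts(
    epochs: Sequence[EEGEpoch],
    cfg: PreprocConfig = None,
) -> tuple[list[EEGEpoch], pd.DataFrame]:
    """Threshold rejection with a per-trial reason log.

    A trial is excluded if |VEOG upper − lower| exceeds 250 µV anywhere
    in the epoch, or any scalp channel exceeds ±100 µV.
    """
    cfg = cfg or PreprocConfig()
    kept, log = [], []
    for ep in epochs:
        veog = ep.veog_pair()
        reasons = []
        if np.abs(veog[0] - veog[1]).max() > cfg.veog_reject_uv:
            reasons.append("veog")
        if np.abs(ep.scalp_data()).max() > cfg.scalp_reject_uv:
            reasons.append("scalp")
        if reasons:
            log.append({"trial_uid": ep.trial_uid, "reason": "+".join(reasons)})
        else:
            kept.append(ep)
    return kept, pd.DataFrame(log, columns=["trial_uid", "reason"])


def preprocess_trials(
    records: Sequence[EEGEpoch],
    rts_ms: Sequence[Optional[float]],
    cfg: PreprocConfig = None,
    apply_csd: bool = True,
) -> dict:
    """Run the full chain on a list of continuous trial records.

    Returns a dict with cue-locked, evidence-locked and response-locked
    epoch lists (rejection run separately for cue- and evidence-locked
    sets), the bad-channel set, and the rejection logs.
    """
    cfg = cfg or PreprocConfig()
    filtered = [detrend_filter(r, cfg) for r in records]
    stacked = np.stack([f.data for f in filtered])
    bad = detect_bad_channels(stacked, filtered[0].montage, cfg)
    cleaned = [rereference_average(interpolate_channels(f, bad, cfg)) for f in filtered]

    cue_eps = [epoch_and_baseline(c, "cue", cfg) for c in cleaned]
    ev_eps = [epoch_and_baseline(c, "evidence", cfg) for c in cleaned]
    cue_kept, cue_log = reject_artifacts(cue_eps, cfg)
    ev_kept, ev_log = reject_artifacts(ev_eps, cfg)

    resp_kept = []
    ev_by_uid = {e.trial_uid: e for e in ev_kept}
    for ep, rt in zip(ev_eps, rts_ms):
        if ep.trial_uid in ev_by_uid and rt is not None:
            r = cut_response_locked(ev_by_uid[ep.trial_uid], rt, cfg)
            if r is not None:
                resp_kept.append(r)

    if apply_csd:
        M = csd_matrix(records[0].montage, cfg)  # one solve, reused per epoch

        def _apply(ep: EEGEpoch) -> EEGEpoch:
            out = ep.data.copy()
            out[: ep.montage.n_scalp] = M @ out[: ep.montage.n_scalp]
            return EEGEpoch(out, ep.t0_ms, ep.alignment, ep.montage,
                            ep.trial_uid, ep.fs_hz)

        cue_kept = [_apply(e) for e in cue_kept]
        ev_kept = [_apply(e) for e in ev_kept]
        resp_kept = [_apply(e) for e in resp_kept]

    return {
        "cue": cue_kept, "evidence": ev_kept, "response": resp_kept,
        "bad_channels": bad, "rejection_log": pd.concat(
            [cue_log.assign(epoch_type="cue"), ev_log.assign(epoch_type="evidence")],
            ignore_index=True),
    }
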