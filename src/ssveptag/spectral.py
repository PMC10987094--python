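"""STFT-based extraction of SSVEP, mu-beta and alpha measures.

The short-time Fourier transform uses a rectangular taper so on-bin
sinusoid amplitudes are preserved exactly; a 400 ms window (MB/SSVEP)
gives ~2.5 Hz bins with the two tag frequencies within 0.03 Hz of bin
centres, and a 360 ms window is used for alpha. Windows advance in 50 ms
steps and each estimate is mapped to the window midpoint. The SSVEP is
normalised by subtracting the mean amplitude of neighbouring bins
(excluding both tag bins), which cancels the local broadband floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EEGEpoch, LEFT_CENTRAL, Montage, RIGHT_CENTRAL

SSVEP_WINDOW_MS = 400.0
ALPHA_WINDOW_MS = 360.0
STEP_MS = 50.0
TAG_FREQS = (20.0, 25.0)
MB_BAND = (8.0, 30.0)
ALPHA_BAND = (8.0, 14.0)


@dataclass
class SpectralEstimate:
    """Time × frequency amplitude map (µV per bin, rectangular taper)."""

    amplitude: np.ndarray  # (n_times, n_freqs), >= 0
    times_ms: np.ndarray   # window midpoints on the epoch's time axis
    freqs_hz: np.ndarray   # bin centres, spacing fs / n_window
    window_ms: float
    step_ms: float

    def freq_index(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - f_hz)))

    def band_indices(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return np.where((self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz))[0]


@dataclass
class AmplitudeSeries:
    """A per-window amplitude time series on the STFT midpoint axis."""

    times_ms: np.ndarray
    values: np.ndarray

    def window_mean(self, start_ms: float, stop_ms: float) -> float:
        """Mean over midpoints in [start_ms, stop_ms)."""
        sel = (self.times_ms >= start_ms) & (self.times_ms < stop_ms)
        if not sel.any():
            raise ValueError("no STFT midpoints inside the window")
        return float(self.values[sel].mean())


def stft_amplitude(
    epoch: EEGEpoch,
    channels: Sequence[str],
    window_ms: float = SSVEP_WINDOW_MS,
    step_ms: float = STEP_MS,
    combine: str = "signal",
) -> SpectralEstimate:
    """Sliding-window amplitude spectrum of the selected channels.

    Amplitude is scaled so a unit-amplitude on-bin sinusoid yields 1
    (``2 |X_k| / N``). ``combine='signal'`` averages channels before the
    transform (default); ``'amplitude'`` averages the per-channel
    amplitude spectra instead.
    """
    if combine not in ("signal", "amplitude"):
        raise ValueError("combine must be 'signal' or 'amplitude'")
    idx = epoch.montage.indices(channels)
    fs = epoch.fs_hz
    n_win = int(round(window_ms * fs / 1000.0))
    if n_win > epoch.n_samples:
        raise ValueError("STFT window longer than the epoch")
    step = step_ms * fs / 1000.0
    n_pos = int(np.floor((epoch.n_samples - n_win) / step)) + 1
    starts = np.round(np.arange(n_pos) * step).astype(int)

    x = epoch.data[idx]  # (n_ch, n_samples)
    segs = np.stack([x[:, s : s + n_win] for s in starts])  # (n_pos, n_ch, n_win)
    if combine == "signal":
        segs = segs.mean(axis=1)                       # (n_pos, n_win)
        amp = np.abs(np.fft.rfft(segs, axis=-1)) * 2.0 / n_win
    else:
        per_ch = np.abs(np.fft.rfft(segs, axis=-1)) * 2.0 / n_win
        amp = per_ch.mean(axis=1)
    amp[..., 0] /= 2.0  # DC has no conjugate bin

    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    mids = epoch.t0_ms + 1000.0 * (starts + n_win / 2.0) / fs
    return SpectralEstimate(amp, mids, freqs, window_ms, step_ms)


def ssvep_normalized(
    spec: SpectralEstimate,
    tag_hz: float,
    n_neighbours: int = 2,
) -> AmplitudeSeries:
    """Tag-bin amplitude minus the mean of neighbouring bins.

    The ``n_neighbours`` nearest bins on each side are used, skipping
    both tag bins; the result estimates the stimulus-driven amplitude
    above the local broadband floor and may be negative.
    """
    if float(tag_hz) not in TAG_FREQS:
        raise ValueError(f"tag frequency must be one of {TAG_FREQS}")
    excluded = {spec.freq_index(f) for f in TAG_FREQS}
    k = spec.freq_index(tag_hz)
    n_bins = len(spec.freqs_hz)

    neigh = []
    for direction in (-1, +1):
        found, j = [], k
        while len(found) < n_neighbours:
            j += direction
            if j < 0 or j >= n_bins:
                raise ValueError("neighbour bins exceed the spectrum")
            if j in excluded:
                continue
            found.append(j)
        neigh.extend(found)

    values = spec.amplitude[:, k] - spec.amplitude[:, neigh].mean(axis=1)
    return AmplitudeSeries(spec.times_ms.copy(), values)


def marginal_ssvep(target: AmplitudeSeries, nontarget: AmplitudeSeries) -> AmplitudeSeries:
    """Target minus non-target SSVEP amplitude (the evidence read-out)."""
    if len(target.times_ms) != len(nontarget.times_ms) or not np.allclose(
        target.times_ms, nontarget.times_ms
    ):
        raise ValueError("target and non-target series are on different time axes")
    return AmplitudeSeries(target.times_ms.copy(), target.values - nontarget.values)


def trial_ssvep_measures(
    epoch: EEGEpoch,
    channels: Sequence[str],
    target_tag_hz: float,
    n_neighbours: int = 2,
    combine: str = "signal",
) -> dict[str, AmplitudeSeries]:
    """Target, non-target and marginal SSVEP series for one trial."""
    spec = stft_amplitude(epoch, channels, SSVEP_WINDOW_MS, STEP_MS, combine)
    other = TAG_FREQS[0] if float(target_tag_hz) == TAG_FREQS[1] else TAG_FREQS[1]
    tgt = ssvep_normalized(spec, target_tag_hz, n_neighbours)
    non = ssvep_normalized(spec, other, n_neighbours)
    return {"target": tgt, "nontarget": non, "marginal": marginal_ssvep(tgt, non)}


def band_amplitude_excluding_tags(spec: SpectralEstimate,
                                  lo_hz: float, hi_hz: float) -> AmplitudeSeries:
    band = spec.band_indices(lo_hz, hi_hz)
    excluded = {spec.freq_index(f) for f in TAG_FREQS}
    use = [b for b in band if b not in excluded]
    return AmplitudeSeries(spec.times_ms.copy(), spec.amplitude[:, use].mean(axis=1))


def mu_beta(
    epoch: EEGEpoch,
    left_channels: Sequence[str],
    right_channels: Sequence[str],
    reference_side: str,
    window_ms: float = SSVEP_WINDOW_MS,
    step_ms: float = STEP_MS,
) -> dict[str, AmplitudeSeries]:
    """Contra/ipsilateral mu-beta (8–30 Hz) amplitude per hemisphere.

    The 20 and 25 Hz tag bins are excluded from the band so SSVEP energy
    cannot leak into the motor measure. ``reference_side`` is the cue
    direction on cued trials and the correct-response side on neutral
    trials; "contra" is the hemisphere opposite that side.
    """
    if reference_side not in ("left", "right"):
        raise ValueError("reference_side must be 'left' or 'right'")
    spec_l = stft_amplitude(epoch, left_channels, window_ms, step_ms)
    spec_r = stft_amplitude(epoch, right_channels, window_ms, step_ms)
    amp_l = band_amplitude_excluding_tags(spec_l, *MB_BAND)
    amp_r = band_amplitude_excluding_tags(spec_r, *MB_BAND)
    if reference_side == "left":
        contra, ipsi = amp_r, amp_l
    else:
        contra, ipsi = amp_l, amp_r
    lat = AmplitudeSeries(contra.times_ms.copy(), contra.values - ipsi.values)
    return {"contra": contra, "ipsi": ipsi, "lateralization": lat}


def alpha_band(
    epoch: EEGEpoch,
    channels: Sequence[str],
    window_ms: float = ALPHA_WINDOW_MS,
    step_ms: float = STEP_MS,
) -> AmplitudeSeries:
    """Mean 8–14 Hz amplitude over occipito-parietal midline channels."""
    spec = stft_amplitude(epoch, channels, window_ms, step_ms)
    band = spec.band_indices(*ALPHA_BAND)
    return AmplitudeSeries(spec.times_ms.copy(), spec.amplitude[:, band].mean(axis=1))


# ---------------------------------------------------------------------------
# data-driven electrode selection

def select_ssvep_electrodes(
    epochs: Sequence[EEGEpoch],
    target_tags: Sequence[float],
    candidate_pool: Sequence[str],
    window_ms: tuple[float, float] = (200.0, 1800.0),
    n_select: int = 2,
) -> list[str]:
    """Rank candidates by target-vs-non-target discrimination; keep top 2.

    For each candidate channel the mean normalized marginal SSVEP over
    200:1800 ms after evidence onset is averaged across trials; ties are
    broken by channel order in the pool.
    """
    if len(candidate_pool) < n_select:
        raise ValueError("candidate pool smaller than the number to select")
    scores = np.zeros(len(candidate_pool))
    for ep, tag in zip(epochs, target_tags):
        for i, ch in enumerate(candidate_pool):
            m = trial_ssvep_measures(ep, [ch], tag)
            scores[i] += m["marginal"].window_mean(*window_ms)
    scores /= max(len(list(epochs)), 1)
    order = np.lexsort((np.arange(len(candidate_pool)), -scores))
    return [candidate_pool[i] for i in order[:n_select]]


def select_mb_electrodes(
    response_epochs: Sequence[EEGEpoch],
    response_sides: Sequence[str],
    left_pool: Sequence[str] = tuple(LEFT_CENTRAL),
    right_pool: Sequence[str] = tuple(RIGHT_CENTRAL),
    n_select: int = 2,
    slope_window_ms: float = 400.0,
) -> dict:
    """Rank-sum selection of mu-beta electrodes per hemisphere.

    Each candidate is scored on (1) the contra-minus-ipsilateral
    amplitude difference at the response (desynchronisation makes this
    negative; more negative ranks higher) and (2) the slope of its
    amplitude over the 400 ms preceding contralateral responses (falling
    amplitude ranks higher). The two rank lists are summed and the top
    ``n_select`` per hemisphere returned; a low-confidence flag is set
    when no candidate shows a negative lateralization at response.
    """
    def hemisphere_scores(pool, contra_side):
        diff = np.zeros(len(pool))
        slope = np.zeros(len(pool))
        n_contra = 0
        for ep, side in zip(response_epochs, response_sides):
            spec = {ch: band_amplitude_excluding_tags(
                stft_amplitude(ep, [ch]), *MB_BAND) for ch in pool}
            at_resp = {ch: s.values[np.argmin(np.abs(s.times_ms))]
                       for ch, s in spec.items()}
            is_contra = side == contra_side
            for i, ch in enumerate(pool):
                diff[i] += at_resp[ch] if is_contra else -at_resp[ch]
            if is_contra:
                n_contra += 1
                for i, ch in enumerate(pool):
                    s = spec[ch]
                    sel = (s.times_ms >= -slope_window_ms) & (s.times_ms < 0)
                    if sel.sum() >= 2:
                        slope[i] += np.polyfit(
                            s.times_ms[sel], s.values[sel], 1)[0]
        if n_contra:
            slope /= n_contra
        n_pairs = max(len(list(response_epochs)), 1)
        diff /= n_pairs
        return diff, slope

    out = {"low_confidence": False}
    for hemi, pool, contra_side in (("left", list(left_pool), "right"),
                                    ("right", list(right_pool), "left")):
        if len(pool) < n_select:
            raise ValueError(f"{hemi} pool smaller than n_select")
        diff, slope = hemisphere_scores(pool, contra_side)
        # smaller (more negative) difference and slope are better
        rank_sum = np.argsort(np.argsort(diff)) + np.argsort(np.argsort(slope))
        order = np.lexsort((np.arange(len(pool)), rank_sum))
        out[hemi] = [pool[i] for i in order[:n_select]]
        if diff.min() >= 0:
            out["low_confidence"] = True
    return out
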