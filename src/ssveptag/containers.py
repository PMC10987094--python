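"""In-memory containers shared across the pipeline: montage and epochs."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

FS_HZ = 512

# epoch spans (ms, half-open) relative to their alignment event
EPOCH_SPANS = {
    "cue": (-1700, 500),       # relative to evidence onset
    "evidence": (-400, 2000),  # relative to evidence onset
    "response": (-600, 400),   # relative to the response
}
BASELINE_WINDOWS = {
    "cue": (-1400, -1200),
    "evidence": (-600, -400),
}

# 32-channel scalp layout (10-05 names) plus the VEOG pair
DEFAULT_SCALP_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2", "Iz",
]
VEOG_CHANNELS = ["VEOGU", "VEOGL"]

OCCIPITAL_POOL = ["P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4", "O1", "Oz", "O2", "Iz"]
CENTRAL_POOL = ["FC5", "FC1", "FC2", "FC6", "C3", "C4", "CP5", "CP1", "CP2", "CP6"]
ALPHA_MIDLINE = ["Pz", "POz", "Oz"]
LEFT_CENTRAL = ["FC5", "FC1", "C3", "CP5", "CP1"]
RIGHT_CENTRAL = ["FC6", "FC2", "C4", "CP6", "CP2"]


@dataclass
class Montage:
    """Channel labels with unit-sphere positions; VEOG carries no position."""

    names: list[str]
    positions: np.ndarray  # (n_scalp, 3) unit vectors, scalp channels only
    veog: list[str] = field(default_factory=lambda: list(VEOG_CHANNELS))

    @property
    def all_names(self) -> list[str]:
        return self.names + self.veog

    @property
    def n_scalp(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.all_names.index(name)

    def indices(self, names: Sequence[str]) -> list[int]:
        return [self.index(n) for n in names]

    def scalp_indices(self) -> list[int]:
        return list(range(self.n_scalp))

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]


def _fit_sphere_center(pos: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud."""
    A = np.c_[2 * pos, np.ones(len(pos))]
    b = (pos ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def default_montage(channels: Optional[Sequence[str]] = None) -> Montage:
    """Standard 10-05 positions projected onto the unit sphere."""
    import mne

    channels = list(channels) if channels is not None else list(DEFAULT_SCALP_CHANNELS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pos = np.array([ch_pos[c] for c in channels], dtype=float)
    pos = pos - _fit_sphere_center(pos)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(names=channels, positions=pos)


@dataclass
class EEGEpoch:
    """channels x samples amplitude matrix (µV) with timing metadata.

    ``t0_ms`` is the time of the first sample relative to the alignment
    event; sample times are ``t0_ms + 1000 * k / fs_hz``.
    """

    data: np.ndarray
    t0_ms: float
    alignment: str  # cue | evidence | response | continuous
    montage: Montage
    trial_uid: Optional[str] = None
    fs_hz: int = FS_HZ

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")
        if self.data.shape[0] != len(self.montage.all_names):
            raise ValueError("channel count does not match montage")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs_hz

    def sample_index(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms`` (half-open windows)."""
        return int(np.ceil((t_ms - self.t0_ms) * self.fs_hz / 1000.0 - 1e-9))

    def crop(self, start_ms: float, stop_ms: float, alignment: Optional[str] = None,
             new_zero_ms: float = 0.0) -> "EEGEpoch":
        """Cut [start_ms, stop_ms) on the current time axis.

        ``new_zero_ms`` re-references the time axis of the result (used
        when cutting response-locked epochs out of evidence-locked data).
        """
        i0 = self.sample_index(start_ms)
        i1 = self.sample_index(stop_ms)
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError("crop window exceeds epoch bounds")
        return EEGEpoch(
            data=self.data[:, i0:i1].copy(),
            t0_ms=self.t0_ms + 1000.0 * i0 / self.fs_hz - new_zero_ms,
            alignment=alignment or self.alignment,
            montage=self.montage,
            trial_uid=self.trial_uid,
            fs_hz=self.fs_hz,
        )

    def scalp_data(self) -> np.ndarray:
        return self.data[: self.montage.n_scalp]

    def veog_pair(self) -> np.ndarray:
        idx = self.montage.indices(self.montage.veog)
        return self.data[idx]


def save_epochs(path, epochs: Sequence[EEGEpoch]) -> None:
    """One array file per subject-session plus a JSON sidecar."""
    path = Path(path)
    arr = np.stack([e.data for e in epochs])
    np.save(path.with_suffix(".npy"), arr)
    meta = {
        "fs_hz": epochs[0].fs_hz,
        "t0_ms": epochs[0].t0_ms,
        "alignment": epochs[0].alignment,
        "trial_uids": [e.trial_uid for e in epochs],
        "channel_labels": epochs[0].montage.all_names,
        "scalp_channels": epochs[0].montage.names,
        "veog_channels": epochs[0].montage.veog,
        "positions": epochs[0].montage.positions.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_epochs(path) -> list[EEGEpoch]:
    path = Path(path)
    arr = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    montage = Montage(
        names=meta["scalp_channels"],
        positions=np.array(meta["positions"]),
        veog=meta["veog_channels"],
    )
    return [
        EEGEpoch(
            data=arr[i], t0_ms=meta["t0_ms"], alignment=meta["alignment"],
            montage=montage, trial_uid=meta["trial_uids"][i], fs_hz=meta["fs_hz"],
        )
        for i in range(arr.shape[0])
    ]
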