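import numpy as np
import pytest

from ssveptag.containers import EEGEpoch, Montage, default_montage


@pytest.fixture(scope="session")
def montage() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def toy_montage() -> Montage:
    """16 scalp positions on a spiral over the upper hemisphere."""
    k = np.arange(16)
    z = 0.05 + 0.9 * k / 15.0
    phi = k * np.pi * (3 - np.sqrt(5))
    r = np.sqrt(1 - z**2)
    pos = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    return Montage(names=[f"ch{i:02d}" for i in k], positions=pos)


def make_epoch(data: np.ndarray, montage: Montage, t0_ms: float = 0.0,
               alignment: str = "evidence", fs: int = 512) -> EEGEpoch:
    """Wrap a channels x samples array (scalp-only arrays get zero VEOG)."""
    n_all = len(montage.all_names)
    if data.shape[0] == montage.n_scalp:
        data = np.vstack([data, np.zeros((n_all - montage.n_scalp, data.shape[1]))])
    return EEGEpoch(data=data, t0_ms=t0_ms, alignment=alignment,
                    montage=montage, trial_uid="test", fs_hz=fs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
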