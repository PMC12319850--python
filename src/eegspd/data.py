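"""Trial containers and on-disk formats.

``TrialSet`` is the universal input of the package: a stack of labelled
multichannel epochs with sampling-rate metadata.  Sets round-trip through
HDF5 (datasets ``data`` and ``labels``, attribute ``fs``); an optional EDF
adapter reads raw recordings through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "TrialSet",
    "save_trialset",
    "load_trialset",
    "load_edf",
    "save_spd_batch",
    "load_spd_batch",
]


@dataclass
class TrialSet:
    """Labelled multichannel epochs.

    ``X`` has shape (n_trials, Ne, Nt); ``y`` integer class labels; ``fs``
    the sampling rate in Hz.
    """

    X: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 3:
            raise ValueError(f"X must be (n_trials, Ne, Nt), got {self.X.shape}")
        if len(self.X) != len(self.y):
            raise ValueError("label count does not match trial count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("trials contain non-finite entries")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_electrodes(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]

    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def save_trialset(path: str | Path, trials: TrialSet) -> None:
    """Write a trial set to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.X)
        f.create_dataset("labels", data=trials.y)
        f.attrs["fs"] = float(trials.fs)


def load_trialset(path: str | Path) -> TrialSet:
    """Read a trial set from an HDF5 container."""
    with h5py.File(path, "r") as f:
        return TrialSet(X=f["data"][...], y=f["labels"][...], fs=float(f.attrs["fs"]))


def load_edf(path: str | Path, epoch_seconds: float, labels: np.ndarray) -> TrialSet:
    """Optional EDF adapter: slice a raw EDF recording into fixed-length epochs.

    Requires :mod:`mne` (optional dependency); labels must match the number
    of whole epochs in the recording.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    nt = int(round(epoch_seconds * fs))
    n_epochs = data.shape[1] // nt
    labels = np.asarray(labels)
    if len(labels) != n_epochs:
        raise ValueError(f"{len(labels)} labels for {n_epochs} epochs")
    X = data[:, : n_epochs * nt].reshape(data.shape[0], n_epochs, nt).transpose(1, 0, 2)
    return TrialSet(X=X, y=labels, fs=fs)


def save_spd_batch(
    path: str | Path, mats: np.ndarray, block_sizes: list[int] | None = None
) -> None:
    """Write a stack of SPD matrices to HDF5 (block sizes as an attribute)."""
    mats = np.asarray(mats, dtype=float)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("matrices", data=mats)
        if block_sizes is not None:
            d.attrs["block_sizes"] = np.asarray(block_sizes, dtype=int)


def load_spd_batch(path: str | Path) -> tuple[np.ndarray, list[int] | None]:
    """Read a stack of SPD matrices and optional block sizes from HDF5."""
    with h5py.File(path, "r") as f:
        d = f["matrices"]
        sizes = d.attrs.get("block_sizes")
        return d[...], None if sizes is None else [int(b) for b in sizes]
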