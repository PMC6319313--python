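"""Epoched-data container and HDF5 / delimited-text I/O.

The canonical in-memory object is :class:`EpochedDataset`: a
``trials x time x channels`` array of (possibly PCA-reduced) sensor data
paired with one stimulus-feature row per trial, optional per-trial reaction
times and subject labels, and the sampling rate.  Trials are axis 0
everywhere in the package.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = ["EpochedDataset", "read_dataset", "write_dataset"]


@dataclasses.dataclass
class EpochedDataset:
    """Trial-epoched multichannel data with per-trial stimulus features.

    Parameters
    ----------
    X : ndarray, shape (n_trials, n_timepoints, n_channels)
        Sensor (or component) data.
    Y : ndarray, shape (n_trials, n_features)
        Stimulus features, constant within a trial (e.g. sine/cosine of a
        grating angle).
    sampling_rate : float
        Samples per second.
    rt : ndarray, shape (n_trials,), optional
        Reaction time in seconds; NaN marks trials without a button press.
    subject : ndarray, shape (n_trials,), optional
        Subject/session label per trial, used to build group CV folds.
    """

    X: np.ndarray
    Y: np.ndarray
    sampling_rate: float
    rt: np.ndarray | None = None
    subject: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 3:
            raise ValueError(f"X must be trials x time x channels, got ndim={self.X.ndim}")
        if self.Y.ndim != 2:
            raise ValueError(f"Y must be trials x features, got ndim={self.Y.ndim}")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"trial count mismatch: X has {self.X.shape[0]} trials, Y has {self.Y.shape[0]}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if not np.isfinite(self.Y).all():
            raise ValueError("Y contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
            if self.rt.shape != (self.X.shape[0],):
                raise ValueError("rt must have one entry per trial")
            finite = self.rt[np.isfinite(self.rt)]
            if (finite <= 0).any():
                raise ValueError("reaction times must be positive where present")
        if self.subject is not None:
            self.subject = np.asarray(self.subject)
            if self.subject.shape != (self.X.shape[0],):
                raise ValueError("subject must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[1]

    @property
    def n_channels(self) -> int:
        return self.X.shape[2]

    @property
    def n_features(self) -> int:
        return self.Y.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Within-trial time axis in seconds (0 at the first sample)."""
        return np.arange(self.n_timepoints) / self.sampling_rate

    def subset(self, trials: np.ndarray) -> "EpochedDataset":
        """Return a copy restricted to the given trial indices/mask."""
        trials = np.asarray(trials)
        return EpochedDataset(
            X=self.X[trials],
            Y=self.Y[trials],
            sampling_rate=self.sampling_rate,
            rt=None if self.rt is None else self.rt[trials],
            subject=None if self.subject is None else self.subject[trials],
        )


def write_dataset(path: str | Path, data: EpochedDataset, *, extra: dict | None = None) -> Path:
    """Write an :class:`EpochedDataset` (plus optional extra arrays) to HDF5.

    Layout: ``/X`` (trials x time x channels, float64), ``/Y``
    (trials x features), optional ``/rt`` and ``/subject``; scalar metadata as
    root attributes.  ``extra`` maps dataset names (e.g. ``state_path``,
    ``true_weights``) to arrays stored alongside.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X.astype(np.float64))
        f.create_dataset("Y", data=data.Y.astype(np.float64))
        if data.rt is not None:
            f.create_dataset("rt", data=data.rt.astype(np.float64))
        if data.subject is not None:
            subj = np.asarray(data.subject)
            if subj.dtype.kind in "US":
                subj = subj.astype(h5py.string_dtype())
            f.create_dataset("subject", data=subj)
        f.attrs["sampling_rate"] = float(data.sampling_rate)
        for name, arr in (extra or {}).items():
            f.create_dataset(name, data=np.asarray(arr))
    return path


def _read_hdf5(path: Path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        for required in ("X", "Y"):
            if required not in f:
                raise KeyError(f"required dataset /{required} missing from {path}")
        X = f["X"][()]
        Y = f["Y"][()]
        rt = f["rt"][()] if "rt" in f else None
        subject = f["subject"][()] if "subject" in f else None
        if subject is not None and subject.dtype.kind == "O":
            subject = subject.astype(str)
        fs = float(f.attrs.get("sampling_rate", 1.0))
    return EpochedDataset(X=X, Y=Y, sampling_rate=fs, rt=rt, subject=subject)


def _read_manifest_dir(path: Path) -> EpochedDataset:
    """Read a directory of delimited-text matrices described by manifest.yaml.

    The manifest gives the shape and the file names; ``X`` is stored as a
    (trials*time) x channels CSV in trial-major order.
    """
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    shape = (int(manifest["n_trials"]), int(manifest["n_timepoints"]), int(manifest["n_channels"]))
    X = np.loadtxt(path / manifest["X"], delimiter=",", ndmin=2).reshape(shape)
    Y = np.loadtxt(path / manifest["Y"], delimiter=",", ndmin=2)
    rt = None
    if manifest.get("rt"):
        rt = np.loadtxt(path / manifest["rt"], delimiter=",")
    subject = None
    if manifest.get("subject"):
        subject = np.loadtxt(path / manifest["subject"], delimiter=",", dtype=str)
    return EpochedDataset(
        X=X, Y=Y, sampling_rate=float(manifest["sampling_rate"]), rt=rt, subject=subject
    )


def read_dataset(path: str | Path) -> EpochedDataset:
    """Load an :class:`EpochedDataset` from HDF5 or a manifest directory."""
    path = Path(path)
    if path.is_dir():
        return _read_manifest_dir(path)
    return _read_hdf5(path)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (order-insensitive)."""
    import hashlib

    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
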