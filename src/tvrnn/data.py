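"""Trial-structured multi-channel time-series container and file I/O.

A :class:`TrialSet` holds a labelled tensor of shape
``[trials, time points, channels]`` — the canonical in-memory object for
trial-based neural decoding — together with the sampling rate and the index
of behavior onset on the time axis.  Datasets round-trip through HDF5 and
NPZ containers with fixed key names (``X``, ``y``) so that simulated and
real recordings share one format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract; names the field."""


@dataclasses.dataclass
class TrialSet:
    """Labelled multi-channel trials anchored to behavior onset.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_timepoints, n_channels)
        Real-valued signal; must be finite everywhere.
    labels : ndarray, shape (n_trials,)
        Binary labels: 1 = 'behavior', 0 = 'control'.
    sampling_rate : float
        Time points per second; strictly positive.
    t_zero_index : int
        Index of behavior onset on the time axis.  For simulated trials this
        is the last time point (the class is decided by the whole sequence);
        for real recordings it anchors the "seconds before behavior" axis.
    channel_names : sequence of str, optional
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float = 30.0
    t_zero_index: int | None = None
    channel_names: Sequence[str] | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D [trials, time, channels], got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError(
                f"labels: expected shape ({self.data.shape[0]},), got {self.labels.shape}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")
        self.labels = self.labels.astype(np.int8)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.t_zero_index is None:
            self.t_zero_index = self.data.shape[1] - 1
        if not 0 <= self.t_zero_index < self.data.shape[1]:
            raise ValidationError(
                f"t_zero_index {self.t_zero_index} outside [0, {self.data.shape[1]})"
            )
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValidationError("channel_names length does not match channel axis")

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def time_seconds(self) -> np.ndarray:
        """Time axis in seconds relative to behavior onset (negative = before)."""
        idx = np.arange(self.n_timepoints)
        return (idx - self.t_zero_index) / self.sampling_rate

    def subset(self, indices: np.ndarray) -> "TrialSet":
        """New TrialSet restricted to the given trial indices."""
        return TrialSet(
            data=self.data[indices],
            labels=self.labels[indices],
            sampling_rate=self.sampling_rate,
            t_zero_index=self.t_zero_index,
            channel_names=self.channel_names,
            meta=dict(self.meta),
        )


# -- file round-trip -----------------------------------------------------

_REQUIRED_KEYS = ("X", "y")


def write_trials(trials: TrialSet, path: str | Path) -> Path:
    """Write a TrialSet to ``.h5``/``.hdf5`` or ``.npz`` (by extension)."""
    path = Path(path)
    spec_json = json.dumps(trials.meta, default=str)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=trials.data.astype(np.float32))
            f.create_dataset("y", data=trials.labels.astype(np.int8))
            f.attrs["sampling_rate"] = trials.sampling_rate
            f.attrs["t_zero_index"] = trials.t_zero_index
            f.attrs["spec"] = spec_json
            if trials.channel_names is not None:
                f.attrs["channel_names"] = [str(c) for c in trials.channel_names]
    elif path.suffix == ".npz":
        extra = {}
        if trials.channel_names is not None:
            extra["channel_names"] = np.asarray(trials.channel_names, dtype=object)
        np.savez(
            path,
            X=trials.data.astype(np.float32),
            y=trials.labels.astype(np.int8),
            sampling_rate=np.float64(trials.sampling_rate),
            t_zero_index=np.int64(trials.t_zero_index),
            spec=np.str_(spec_json),
            **extra,
        )
    else:
        raise ValidationError(f"unsupported output format: {path.suffix!r}")
    return path


def read_trials(path: str | Path) -> TrialSet:
    """Read a TrialSet written by :func:`write_trials`; validates on load."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            for key in _REQUIRED_KEYS:
                if key not in f:
                    raise ValidationError(f"missing dataset {key!r} in {path}")
            data = f["X"][...]
            labels = f["y"][...]
            sr = float(f.attrs.get("sampling_rate", 30.0))
            tz = int(f.attrs["t_zero_index"]) if "t_zero_index" in f.attrs else None
            names = f.attrs.get("channel_names")
            meta = json.loads(f.attrs.get("spec", "{}"))
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=True) as f:
            for key in _REQUIRED_KEYS:
                if key not in f:
                    raise ValidationError(f"missing array {key!r} in {path}")
            data = f["X"]
            labels = f["y"]
            sr = float(f["sampling_rate"]) if "sampling_rate" in f else 30.0
            tz = int(f["t_zero_index"]) if "t_zero_index" in f else None
            names = f["channel_names"].tolist() if "channel_names" in f else None
            meta = json.loads(str(f["spec"])) if "spec" in f else {}
    else:
        raise ValidationError(f"unsupported input format: {path.suffix!r}")
    if names is not None:
        names = [str(c) for c in names]
    return TrialSet(
        data=np.asarray(data, dtype=np.float64),
        labels=np.asarray(labels),
        sampling_rate=sr,
        t_zero_index=tz,
        channel_names=names,
        meta=meta,
    )
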