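"""Shared in-memory containers for epoched EEG and time-resolved neural RDMs,
with an HDF5 serialization layout.

HDF5 layout
-----------
Epochs (one subject per file or group)::

    /epochs/data        float32, trials x channels x samples
    /epochs/conditions  int64, condition id per trial
    /epochs/chunks      int64, cross-validation chunk id per trial (0-based)
    /epochs/times_ms    float64, sample times relative to stimulus onset
    /epochs/sfreq       scalar attribute on /epochs

Neural RDM stacks::

    /rdm/vector         float64, bins x n_pairs (pairwise decoding accuracy)
    /rdm/labels         int64, condition ids in RDM order
    /rdm/time_ms        float64, bin-center times
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochSet", "NeuralRDMStack", "save_epochs", "load_epochs",
           "save_stack", "load_stack"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG for one subject.

    data : trials x channels x samples (arbitrary amplitude units)
    conditions : condition id per trial
    chunks : cross-validation chunk id per trial
    times_ms : per-sample time relative to stimulus onset
    """

    data: np.ndarray = field(repr=False)
    conditions: np.ndarray
    chunks: np.ndarray
    sfreq: float
    times_ms: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.chunks = np.asarray(self.chunks)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        n_trials, _, n_samples = self.data.shape
        if len(self.conditions) != n_trials or len(self.chunks) != n_trials:
            raise ValueError("per-trial metadata length mismatch")
        if len(self.times_ms) != n_samples:
            raise ValueError("time axis length does not match sample count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def condition_labels(self) -> np.ndarray:
        """Sorted unique condition ids (the RDM label order)."""
        return np.unique(self.conditions)


@dataclass
class NeuralRDMStack:
    """Per-time-bin RDM vectors of pairwise decoding accuracies for one subject.

    vectors : bins x n_pairs, proportion correct (chance 0.5)
    labels : condition ids, RDM order
    times_ms : bin-center times (the center sample of each window)
    """

    vectors: np.ndarray = field(repr=False)
    labels: np.ndarray
    times_ms: np.ndarray
    subject: int = 0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("stack must be bins x pairs")
        n = len(self.labels)
        if self.vectors.shape[1] != n * (n - 1) // 2:
            raise ValueError("pair count does not match label count")
        if self.vectors.shape[0] != len(self.times_ms):
            raise ValueError("bin count does not match time axis")

    @property
    def n_bins(self) -> int:
        return self.vectors.shape[0]


def save_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data.astype(np.float32))
        g.create_dataset("conditions", data=epochs.conditions.astype(np.int64))
        g.create_dataset("chunks", data=epochs.chunks.astype(np.int64))
        g.create_dataset("times_ms", data=epochs.times_ms)
        g.attrs["sfreq"] = float(epochs.sfreq)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f["epochs"]
        return EpochSet(
            data=g["data"][()],
            conditions=g["conditions"][()],
            chunks=g["chunks"][()],
            sfreq=float(g.attrs["sfreq"]),
            times_ms=g["times_ms"][()],
        )


def save_stack(path, stack: NeuralRDMStack) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("rdm")
        g.create_dataset("vector", data=stack.vectors)
        g.create_dataset("labels", data=np.asarray(stack.labels, dtype=np.int64))
        g.create_dataset("time_ms", data=stack.times_ms)
        g.attrs["subject"] = int(stack.subject)


def load_stack(path) -> NeuralRDMStack:
    with h5py.File(path, "r") as f:
        g = f["rdm"]
        return NeuralRDMStack(
            vectors=g["vector"][()],
            labels=g["labels"][()],
            times_ms=g["time_ms"][()],
            subject=int(g.attrs.get("subject", 0)),
        )
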