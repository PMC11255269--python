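"""File formats: trial CSVs and fluorescence HDF5, with alignment validation.

Trial CSV columns: ``session, trial_index, phase, stimulus, trial_type,
action, outcome, first_lick_s, n_licks`` (comma-separated, UTF-8, one trial
per row).  Fluorescence HDF5: dataset ``F`` of shape (neurons, trials,
frames) with attributes ``frame_rate`` and ``t0_frame``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "session",
    "trial_index",
    "phase",
    "stimulus",
    "trial_type",
    "action",
    "outcome",
    "first_lick_s",
    "n_licks",
]


class SchemaError(ValueError):
    """File does not match the documented format."""


class AlignmentError(ValueError):
    """Trial table and fluorescence tensor disagree."""


@dataclass
class FluorescenceTensor:
    F: np.ndarray  # (neurons, trials, frames)
    frame_rate: float
    t0_frame: int

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_trials(self) -> int:
        return self.F.shape[1]


@dataclass
class Dataset:
    trials: dict[str, pd.DataFrame]
    fluorescence: dict[str, FluorescenceTensor]
    neuron_ids: list = field(default_factory=list)
    ground_truth: object = None

    def __post_init__(self):
        if len(self.neuron_ids) != len(set(self.neuron_ids)):
            raise SchemaError("neuron_ids must be unique")
        for name, tensor in self.fluorescence.items():
            n_rows = len(self.trials[name])
            if tensor.n_trials != n_rows:
                raise AlignmentError(
                    f"session {name!r}: fluorescence has {tensor.n_trials} trials, "
                    f"table has {n_rows}"
                )
            if self.neuron_ids and tensor.n_neurons != len(self.neuron_ids):
                raise AlignmentError(
                    f"session {name!r}: {tensor.n_neurons} neurons vs "
                    f"{len(self.neuron_ids)} neuron_ids"
                )

    @property
    def sessions(self) -> list[str]:
        return list(self.trials)


def load_dataset(trials_path, fluo_path) -> Dataset:
    """Read a trial CSV and fluorescence HDF5 into a validated Dataset."""
    trials = pd.read_csv(trials_path)
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial CSV missing columns: {missing}")
    by_session = {name: g.reset_index(drop=True) for name, g in trials.groupby("session", sort=False)}

    fluo = {}
    n_neurons = None
    with h5py.File(fluo_path, "r") as fh:
        for name in by_session:
            if name not in fh:
                raise SchemaError(f"HDF5 missing group for session {name!r}")
            grp = fh[name]
            if "F" not in grp:
                raise SchemaError(f"HDF5 session {name!r} missing dataset 'F'")
            tensor = FluorescenceTensor(
                F=grp["F"][()],
                frame_rate=float(grp.attrs["frame_rate"]),
                t0_frame=int(grp.attrs["t0_frame"]),
            )
            fluo[name] = tensor
            n_neurons = tensor.n_neurons
    return Dataset(trials=by_session, fluorescence=fluo, neuron_ids=list(range(n_neurons or 0)))


def write_dataset(dataset: Dataset, trials_path, fluo_path) -> None:
    """Write a Dataset back to the CSV/HDF5 pair (full float precision)."""
    frames = []
    for name in dataset.sessions:
        t = dataset.trials[name]
        cols = [c for c in REQUIRED_COLUMNS if c in t.columns]
        frames.append(t[cols])
    pd.concat(frames, ignore_index=True).to_csv(trials_path, index=False)
    with h5py.File(fluo_path, "w") as fh:
        for name, tensor in dataset.fluorescence.items():
            grp = fh.create_group(name)
            grp.create_dataset("F", data=tensor.F)
            grp.attrs["frame_rate"] = tensor.frame_rate
            grp.attrs["t0_frame"] = tensor.t0_frame


def write_tensors(path, **arrays) -> None:
    """Write named float arrays (e.g. dff, zscored) to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))
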