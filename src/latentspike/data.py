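"""Trial-structured spike data containers and file I/O.

A trial is a marked point process on [t0, tE]: an ordered sequence of
(spike time, neuron index) events plus the trial start t0 and end tE (the
reaction time), a stimulus-condition label, and optionally the reported
choice.  Times are absolute seconds within the analysed window (window
start = t0).  Neuron indices are 0-based in memory and 1-based in files.

Two on-disk formats are supported: an HDF5 layout
``/trials/<k>/{t0, tE, spike_times, neuron_ids, condition, choice}`` with
attributes ``n_neurons`` and ``time_unit = "s"``, and a line-oriented JSON
dialect for tiny fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np

__all__ = ["Trial", "SpikeData"]


class DataError(ValueError):
    """Raised for malformed spike data."""


@dataclass
class Trial:
    """One trial of a marked point process.

    ``choice`` uses the boundary convention: -1 for the left boundary,
    +1 for the right; ``None`` when unlabelled.
    """

    t0: float
    tE: float
    spike_times: np.ndarray
    neuron_ids: np.ndarray
    condition: int
    choice: Optional[int] = None
    correct: Optional[bool] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.spike_times.shape != self.neuron_ids.shape:
            raise DataError("spike_times and neuron_ids must have equal length")
        if self.tE <= self.t0:
            raise DataError(f"tE={self.tE} must exceed t0={self.t0}")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise DataError("spike times must be ordered")
            if self.spike_times[0] <= self.t0 or self.spike_times[-1] >= self.tE:
                raise DataError("spikes must lie strictly inside (t0, tE)")
            if np.any(self.neuron_ids < 0):
                raise DataError("neuron indices must be non-negative")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.tE - self.t0


@dataclass
class SpikeData:
    """A collection of trials recorded from ``n_neurons`` units."""

    trials: list[Trial]
    n_neurons: int

    def __post_init__(self) -> None:
        for tr in self.trials:
            if tr.neuron_ids.size and tr.neuron_ids.max() >= self.n_neurons:
                raise DataError("neuron index exceeds n_neurons")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def conditions(self) -> list[int]:
        return sorted({tr.condition for tr in self.trials})

    def by_condition(self, condition: int) -> "SpikeData":
        return SpikeData(
            [tr for tr in self.trials if tr.condition == condition], self.n_neurons
        )

    def subset(self, indices: Sequence[int]) -> "SpikeData":
        return SpikeData([self.trials[i] for i in indices], self.n_neurons)

    def split_even_odd(self) -> tuple["SpikeData", "SpikeData"]:
        """Deterministic even/odd split by trial index within each condition."""
        even, odd = [], []
        counters: dict[int, int] = {}
        for tr in self.trials:
            k = counters.get(tr.condition, 0)
            (even if k % 2 == 0 else odd).append(tr)
            counters[tr.condition] = k + 1
        return SpikeData(even, self.n_neurons), SpikeData(odd, self.n_neurons)

    def total_spikes(self, neuron: Optional[int] = None) -> int:
        if neuron is None:
            return sum(tr.n_spikes for tr in self.trials)
        return sum(int(np.sum(tr.neuron_ids == neuron)) for tr in self.trials)

    # ---------------------------------------------------------------- I/O

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["n_neurons"] = self.n_neurons
            f.attrs["time_unit"] = "s"
            g = f.create_group("trials")
            for k, tr in enumerate(self.trials):
                gk = g.create_group(str(k))
                gk.create_dataset("t0", data=tr.t0)
                gk.create_dataset("tE", data=tr.tE)
                gk.create_dataset("spike_times", data=tr.spike_times)
                # 1-based neuron indices on disk
                gk.create_dataset("neuron_ids", data=tr.neuron_ids + 1)
                gk.create_dataset("condition", data=tr.condition)
                gk.create_dataset(
                    "choice", data=0 if tr.choice is None else int(tr.choice)
                )

    @classmethod
    def from_hdf5(cls, path: str) -> "SpikeData":
        with h5py.File(path, "r") as f:
            n_neurons = int(f.attrs["n_neurons"])
            g = f["trials"]
            trials = []
            for k in sorted(g.keys(), key=int):
                gk = g[k]
                choice = int(gk["choice"][()])
                trials.append(
                    Trial(
                        t0=float(gk["t0"][()]),
                        tE=float(gk["tE"][()]),
                        spike_times=np.asarray(gk["spike_times"]),
                        neuron_ids=np.asarray(gk["neuron_ids"]) - 1,
                        condition=int(gk["condition"][()]),
                        choice=None if choice == 0 else choice,
                    )
                )
        return cls(trials, n_neurons)

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as f:
            f.write(json.dumps({"n_neurons": self.n_neurons}) + "\n")
            for tr in self.trials:
                f.write(
                    json.dumps(
                        {
                            "t0": tr.t0,
                            "tE": tr.tE,
                            "spike_times": tr.spike_times.tolist(),
                            "neuron_ids": (tr.neuron_ids + 1).tolist(),
                            "condition": tr.condition,
                            "choice": tr.choice,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str) -> "SpikeData":
        with open(path) as f:
            header = json.loads(f.readline())
            trials = []
            for line in f:
                rec = json.loads(line)
                trials.append(
                    Trial(
                        t0=rec["t0"],
                        tE=rec["tE"],
                        spike_times=np.asarray(rec["spike_times"], dtype=float),
                        neuron_ids=np.asarray(rec["neuron_ids"], dtype=np.int64) - 1,
                        condition=rec["condition"],
                        choice=rec.get("choice"),
                    )
                )
        return cls(trials, int(header["n_neurons"]))
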