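"""Configuration files, model/trace persistence, reports and run manifests."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .grid import build_grid
from .model import LatentModel
from .optimize import FitConfig, FitTrace

__all__ = [
    "load_config",
    "save_config",
    "save_model",
    "load_model",
    "save_trace",
    "load_trace",
    "RunManifest",
    "selection_report",
]

_CONFIG_FIELDS = set(FitConfig().to_dict())


def load_config(path: str) -> FitConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return FitConfig(**raw)


def save_config(config: FitConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)


def _write_model(g: h5py.Group, model: LatentModel) -> None:
    g.create_dataset("forces", data=model.forces)
    g.create_dataset("F0", data=model.F0)
    g.create_dataset("tuning_aux", data=model.tuning_aux)
    g.create_dataset("tuning_C", data=model.tuning_C)
    g.attrs["D"] = model.D
    g.attrs["n_nodes"] = model.grid.n


def _read_model(g: h5py.Group) -> LatentModel:
    grid = build_grid(int(g.attrs["n_nodes"]))
    return LatentModel(
        grid=grid,
        forces=np.asarray(g["forces"]),
        D=float(g.attrs["D"]),
        F0=np.asarray(g["F0"]),
        tuning_aux=np.asarray(g["tuning_aux"]),
        tuning_C=np.asarray(g["tuning_C"]),
    )


def save_model(model: LatentModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        _write_model(f.create_group("model"), model)


def load_model(path: str) -> LatentModel:
    with h5py.File(path, "r") as f:
        return _read_model(f["model"])


def save_trace(trace: FitTrace, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["split_id"] = trace.split_id
        f.attrs["config"] = json.dumps(trace.config.to_dict())
        f.create_dataset("epochs", data=trace.epochs)
        f.create_dataset("loglik", data=trace.loglik)
        f.create_dataset("complexity", data=trace.complexity)
        f.create_dataset("snapshot_epochs", data=np.asarray(trace.snapshot_epochs))
        g = f.create_group("snapshots")
        for k, m in enumerate(trace.snapshots):
            _write_model(g.create_group(str(k)), m)


def load_trace(path: str) -> FitTrace:
    with h5py.File(path, "r") as f:
        trace = FitTrace(
            config=FitConfig.from_dict(json.loads(f.attrs["config"])),
            split_id=int(f.attrs["split_id"]),
            epochs=np.asarray(f["epochs"]),
            loglik=np.asarray(f["loglik"]),
            complexity=np.asarray(f["complexity"]),
            snapshot_epochs=[int(e) for e in np.asarray(f["snapshot_epochs"])],
        )
        g = f["snapshots"]
        trace.snapshots = [_read_model(g[str(k)]) for k in range(len(g))]
    return trace


def selection_report(selection, path: str) -> None:
    """JSON report: M*, the D_JS curve and the outcome label."""
    rep = {
        "M_star": selection.M_star,
        "threshold": selection.threshold,
        "converged": selection.converged,
        "outcome": selection.outcome,
        "pair_complexity": selection.pair_complexity.tolist(),
        "pair_djs": selection.pair_djs.tolist(),
        "D_split1": selection.model1.D,
        "D_split2": selection.model2.D,
    }
    with open(path, "w") as f:
        json.dump(rep, f, indent=1)


def validation_report(rows: list[dict], path: str) -> pd.DataFrame:
    """Per-unit validation metrics as CSV (log-L ratios, R^2, phi, ...)."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline stage."""

    stage: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def add_input(self, name: str, path: str) -> None:
        self.inputs[name] = {"path": path, "sha256_16": _file_hash(path)}

    def save(self, out_dir: str) -> str:
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, f"manifest_{self.stage}.json")
        with open(path, "w") as f:
            json.dump(
                {
                    "stage": self.stage,
                    "seed": self.seed,
                    "config": self.config,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "timings": self.timings,
                    "version": self.version,
                    "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
                },
                f,
                indent=1,
            )
        return path

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as f:
            d = json.load(f)
        d.pop("written", None)
        return cls(**d)
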