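"""HDF5/CSV/YAML persistence for traces, epochs and run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .circstats import EpochSet
from .network import NetworkParams, TrialTrace

__all__ = [
    "save_trace", "load_trace", "save_epochs", "load_epochs",
    "load_config", "params_from_config", "config_hash",
]


def save_trace(path, trace: TrialTrace, group: str = "trial0",
               attrs: dict | None = None) -> None:
    """Write one trial trace to an HDF5 group (rates in Hz, times in s)."""
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("times", "raster", "u", "x", "h_I"):
            if name in g:
                del g[name]
            g.create_dataset(name, data=getattr(trace, name))
        g.attrs["events"] = json.dumps(trace.events)
        if trace.target_angle is not None:
            g.attrs["target_angle"] = trace.target_angle
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def load_trace(path, group: str = "trial0") -> TrialTrace:
    with h5py.File(path, "r") as f:
        g = f[group]
        return TrialTrace(
            times=g["times"][()], raster=g["raster"][()],
            u=g["u"][()], x=g["x"][()], h_I=g["h_I"][()],
            events={k: tuple(v) for k, v in json.loads(g.attrs["events"]).items()},
            target_angle=g.attrs.get("target_angle"),
        )


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an epoch array with labels and times to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        if epochs.angle_labels is not None:
            f.create_dataset("angle_labels", data=epochs.angle_labels)
        if epochs.category_labels is not None:
            f.create_dataset("category_labels",
                             data=np.asarray(epochs.category_labels))
        f.attrs["baseline_window"] = epochs.baseline_window


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()], times=f["times"][()],
            angle_labels=f["angle_labels"][()] if "angle_labels" in f else None,
            category_labels=(f["category_labels"][()]
                             if "category_labels" in f else None),
            baseline_window=tuple(f.attrs.get("baseline_window", (-0.2, -0.05))),
        )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def params_from_config(cfg: dict) -> NetworkParams:
    """Build network parameters from a config mapping, validating field names."""
    known = {f.name for f in dataclasses.fields(NetworkParams)}
    section = cfg.get("network", cfg)
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown network parameter(s): {sorted(unknown)}")
    return NetworkParams(**section)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, recorded in outputs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
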