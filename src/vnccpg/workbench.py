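"""Result serialization, configuration, and run manifests.

Interchange formats are deliberately plain: circuit instances, genotypes,
fitness breakdowns and criteria reports as schema-versioned JSON; traces as
tidy CSV (time, cell, y, output); the architecture as a plain-text edge
list.  Every CLI invocation writes an append-only manifest recording the
config snapshot, seeds and output paths so any run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import CircuitInstance, ParameterRanges
from .dynamics import SimulationConfig, Trace
from .ensemble import CriteriaThresholds
from .evolution import EvolutionConfig
from .fitness import FitnessConstants

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "save_instance",
    "load_instance",
    "save_genotype",
    "load_genotype",
    "trace_to_csv",
    "trace_from_csv",
    "save_json",
    "default_config",
    "load_config",
    "config_hash",
    "write_manifest",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """Payload version does not match what this build reads."""


def _check_version(payload: dict, path) -> None:
    v = payload.get("schema_version")
    if v != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {v!r} not supported (expected "
            f"{SCHEMA_VERSION!r}); migrate the file before loading"
        )


def save_instance(instance: CircuitInstance, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "circuit_instance",
        "cells": instance.cells,
        "tau": instance.tau.tolist(),
        "theta": instance.theta.tolist(),
        "self_weight": instance.self_weight.tolist(),
        "chemical_synapses": [[p, q, w] for p, q, w in instance.chemical_synapses],
        "gap_junctions": [[a, b, g] for a, b, g in instance.gap_junctions],
        "w_avb": instance.w_avb,
        "w_ava": instance.w_ava,
        "tonic": instance.tonic.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_instance(path) -> CircuitInstance:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}, "
                         f"column {exc.colno}: {exc.msg}") from exc
    _check_version(payload, path)
    try:
        return CircuitInstance(
            cells=list(payload["cells"]),
            tau=np.asarray(payload["tau"], float),
            theta=np.asarray(payload["theta"], float),
            self_weight=np.asarray(payload["self_weight"], float),
            chemical_synapses=[(p, q, float(w))
                               for p, q, w in payload["chemical_synapses"]],
            gap_junctions=[(a, b, float(g))
                           for a, b, g in payload["gap_junctions"]],
            w_avb=float(payload["w_avb"]),
            w_ava=float(payload["w_ava"]),
            tonic=np.asarray(payload["tonic"], float),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing field {exc}") from exc


def save_genotype(genotype: np.ndarray, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "genotype",
        "values": [float(x) for x in np.asarray(genotype)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_genotype(path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    _check_version(payload, path)
    return np.asarray(payload["values"], float)


def trace_to_csv(trace: Trace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.12g")


def trace_from_csv(path, theta_by_cell: dict | None = None) -> Trace:
    """Rebuild a Trace from tidy CSV; thetas default to 0 (outputs then
    reflect sigma(y) only) unless supplied."""
    df = pd.read_csv(path)
    cells = list(dict.fromkeys(df["cell"]))
    time = np.asarray(sorted(df["time"].unique()), float)
    y = np.empty((len(time), len(cells)))
    for j, c in enumerate(cells):
        y[:, j] = df.loc[df["cell"] == c].sort_values("time")["y"].to_numpy()
    theta = np.array([(theta_by_cell or {}).get(c, 0.0) for c in cells])
    return Trace(time=time, y=y, cells=cells, theta=theta)


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return asdict(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Every model constant in one editable mapping."""
    return {
        "simulation": asdict(SimulationConfig()),
        "fitness": asdict(FitnessConstants()),
        "ranges": asdict(ParameterRanges()),
        "criteria": asdict(CriteriaThresholds()),
        "evolution": asdict(EvolutionConfig()),
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise KeyError(f"unknown config key {section}.{key}")
                cfg[section][key] = val
    for dotted, val in (overrides or {}).items():
        section, key = dotted.split(".", 1)
        if section not in cfg or key not in cfg[section]:
            raise KeyError(f"unknown config key {dotted}")
        cfg[section][key] = val
    return cfg


def build_objects(cfg: dict):
    """(SimulationConfig, FitnessConstants, ParameterRanges,
    CriteriaThresholds, EvolutionConfig) from a config mapping."""
    ranges = {k: tuple(v) for k, v in cfg["ranges"].items()}
    return (
        SimulationConfig(**cfg["simulation"]),
        FitnessConstants(**cfg["fitness"]),
        ParameterRanges(**ranges),
        CriteriaThresholds(**cfg["criteria"]),
        EvolutionConfig(**cfg["evolution"]),
    )


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir,
    command: str,
    cfg: dict,
    seeds: list[int],
    outputs: list[str],
) -> Path:
    """Append a manifest entry; manifests are never rewritten."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = _time.strftime("%Y%m%dT%H%M%S")
    path = out_dir / f"manifest-{stamp}-{command}.json"
    i = 0
    while path.exists():  # append-only: never clobber
        i += 1
        path = out_dir / f"manifest-{stamp}-{command}-{i}.json"
    save_json({
        "command": command,
        "version": __version__,
        "timestamp": stamp,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "outputs": [str(o) for o in outputs],
    }, path)
    return path
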