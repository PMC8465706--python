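"""Serialization of structures, parameters, fit results and trajectories.

Structured objects go to YAML or JSON (chosen by file extension);
tabular outputs go to tidy CSV.  Every file written through
:func:`write_json`/:func:`write_yaml` with a ``provenance`` argument
embeds the seeds used and a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .fitting import FitResult
from .kinetics import Trajectory, organ_activity
from .parameters import ParameterSet
from .structures import Edge, ModelStructure, Observable

__all__ = [
    "structure_to_dict",
    "structure_from_dict",
    "params_to_dict",
    "params_from_dict",
    "save_model",
    "load_model",
    "fit_result_to_dict",
    "write_trajectory_csv",
    "config_hash",
    "write_json",
    "write_yaml",
]


def structure_to_dict(structure: ModelStructure) -> dict:
    return {
        "compartments": list(structure.compartments),
        "edges": [
            {"source": e.source, "target": e.target, "rate": e.rate}
            for e in structure.edges
        ],
        "observations": {
            organ: {
                "compartments": list(obs.compartments),
                "blood_fraction": obs.fraction,
            }
            for organ, obs in structure.observations.items()
        },
    }


def structure_from_dict(d: Mapping) -> ModelStructure:
    return ModelStructure(
        compartments=tuple(d["compartments"]),
        edges=tuple(
            Edge(e["source"], e["target"], e["rate"]) for e in d["edges"]
        ),
        observations={
            organ: Observable(
                tuple(o["compartments"]), o.get("blood_fraction")
            )
            for organ, o in d.get("observations", {}).items()
        },
    )


def params_to_dict(params: ParameterSet) -> dict:
    return {
        "rates_per_h": dict(params.rates),
        "blood_fractions": dict(params.blood_fractions),
        "decay_constant_per_h": params.lam,
    }


def params_from_dict(d: Mapping) -> ParameterSet:
    return ParameterSet(
        rates=dict(d["rates_per_h"]),
        blood_fractions=dict(d.get("blood_fractions", {})),
        lam=float(d["decay_constant_per_h"]),
    )


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _dump(data: dict, path: Path) -> None:
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(_pyify(data), sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2, default=float))


def _load(path: Path) -> dict:
    text = Path(path).read_text()
    if Path(path).suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_model(
    structure: ModelStructure, params: ParameterSet | None, path: str | Path
) -> None:
    data: dict[str, Any] = {"structure": structure_to_dict(structure)}
    if params is not None:
        data["parameters"] = params_to_dict(params)
    _dump(data, Path(path))


def load_model(path: str | Path) -> tuple[ModelStructure, ParameterSet | None]:
    d = _load(Path(path))
    structure = structure_from_dict(d["structure"])
    params = params_from_dict(d["parameters"]) if "parameters" in d else None
    return structure, params


def fit_result_to_dict(result: FitResult) -> dict:
    return {
        "parameters": params_to_dict(result.params),
        "wrss": result.wrss,
        "n_points": result.n,
        "n_parameters": result.k,
        "goodness_of_fit": result.goodness_of_fit,
        "aicc": result.aicc,
        "seed": result.seed,
        "n_evaluations": result.n_evaluations,
        "dataset_fingerprint": result.dataset_fingerprint,
        "best_objective_trace": list(result.trace),
        "forcing": None if result.forcing is None else asdict(result.forcing),
        "variant": None if result.variant is None else result.variant.tag,
    }


def write_trajectory_csv(
    traj: Trajectory,
    path: str | Path,
    structure: ModelStructure | None = None,
    params: ParameterSet | None = None,
) -> None:
    """Tidy CSV (organ, time_h, activity_pct).

    With a structure and parameters, rows are organ observables; without,
    raw compartment activities.
    """
    rows = []
    if structure is not None and params is not None:
        for organ in structure.observations:
            curve = organ_activity(traj, structure, params, organ)
            for t, a in zip(traj.times, curve):
                rows.append({"organ": organ, "time_h": t, "activity_pct": a})
    else:
        for i, comp in enumerate(traj.compartments):
            for t, a in zip(traj.times, traj.activities[:, i]):
                rows.append({"organ": comp, "time_h": t, "activity_pct": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping (provenance stamp)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _with_provenance(data: dict, provenance: Mapping | None) -> dict:
    if provenance is None:
        return data
    return {
        **data,
        "provenance": {**dict(provenance), "config_hash": config_hash(provenance)},
    }


def write_json(data: dict, path: str | Path, provenance: Mapping | None = None) -> None:
    Path(path).write_text(
        json.dumps(_with_provenance(data, provenance), indent=2, default=float)
    )


def write_yaml(data: dict, path: str | Path, provenance: Mapping | None = None) -> None:
    Path(path).write_text(
        yaml.safe_dump(_pyify(_with_provenance(data, provenance)), sort_keys=False)
    )
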