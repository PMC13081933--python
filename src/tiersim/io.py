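"""Output writing, run configuration files, and reproducibility manifests."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import NetworkConfig, SiphonConfig, StimulusConfig
from .ensemble import EnsembleSummary
from .network import TrialTrace
from .siphon import SiphonTrajectory
from .sweeps import SweepResult

PathLike = Union[str, Path]

TRACE_COLUMNS = [
    "trial_id", "level", "iteration", "delta_sum", "delta_sq", "delta_max",
    "work_cum", "entropy_norm", "lyapunov",
]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def build_manifest(
    *,
    command: str,
    configs: Dict[str, object],
    seeds: Sequence[int] = (),
    derived: Optional[Dict[str, float]] = None,
) -> dict:
    """Reproducibility manifest: config snapshot, seed list, version,
    derived constants, and a timestamp. Everything except the timestamp
    determines the outputs bit-for-bit."""
    return {
        "command": command,
        "software_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "configs": {k: _jsonable(v) for k, v in configs.items()},
        "seeds": [int(s) for s in seeds],
        "derived_constants": dict(derived or {}),
    }


def write_json(payload: dict, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
    return path


def write_traces_csv(traces: Sequence[TrialTrace], path: PathLike) -> Path:
    """Tidy trace table (one row per trial, level, iteration)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.concat([tr.to_frame() for tr in traces], ignore_index=True)
    df[TRACE_COLUMNS].to_csv(path, index=False)
    return path


def write_summary_json(summary: EnsembleSummary, path: PathLike) -> Path:
    return write_json(summary.to_dict(), path)


def write_trajectory_csv(traj: SiphonTrajectory, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, index=False)
    return path


def write_sweep(result: SweepResult, out_dir: PathLike) -> List[Path]:
    """One CSV per sweep table plus a JSON index with its manifest data."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"sweep_{result.name}.csv"
    result.table.to_csv(csv_path, index=False)
    index = {"name": result.name, "meta": result.meta,
             "rows": int(len(result.table)), "csv": csv_path.name}
    if "effect_range" in result.extras:
        index["effect_range"] = result.extras["effect_range"]
    if "main_effects" in result.extras:
        index["main_effects"] = {
            f: {str(k): float(v) for k, v in series.items()}
            for f, series in result.extras["main_effects"].items()
        }
    json_path = write_json(index, out_dir / f"sweep_{result.name}.json")
    return [csv_path, json_path]


def load_run_config(path: PathLike) -> dict:
    """Flat YAML run-configuration file split into typed config objects.

    Recognised top-level keys: ``network``, ``stimulus``, ``siphon``
    (each a mapping of field overrides) and ``n_trials``/``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    if "network" in raw:
        out["network"] = NetworkConfig(**raw["network"])
    if "stimulus" in raw:
        out["stimulus"] = StimulusConfig(**raw["stimulus"])
    if "siphon" in raw:
        out["siphon"] = SiphonConfig(**raw["siphon"])
    for key in ("n_trials", "seed"):
        if key in raw:
            out[key] = int(raw[key])
    return out
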