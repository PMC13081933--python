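"""The six prespecified sensitivity analyses as reusable sweep drivers.

Network-side sweeps (work metric, input regime, activation function) run
seeded ensembles and report the Level 3 vs Level 1 percent elevation of
the area under the per-synapse work curve. Siphon-side sweeps (FFE
grid, compensation factor, factorial interaction) run the deterministic
failure model and report milestone times, failure order, and lead time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import NetworkConfig, SiphonConfig, StimulusConfig
from .ensemble import EnsembleSummary, compare_levels, percent_elevation, run_ensemble
from .siphon import milestones, run_siphon

__all__ = [
    "SweepResult",
    "metric_sweep",
    "input_regime_sweep",
    "ffe_grid_sweep",
    "compensation_sweep",
    "activation_sweep",
    "factorial_interaction_sweep",
    "FFE_CORTEX_GRID",
    "FFE_SUPPORT_GRID",
    "COMPENSATION_VALUES",
]

FFE_CORTEX_GRID = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
FFE_SUPPORT_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)
COMPENSATION_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
FACTORIAL_FFE_RATIOS = (2.0, 3.0, 4.0)
FACTORIAL_COMP_FACTORS = (1.0, 2.0, 3.0)
FACTORIAL_SIZES = (500.0, 1000.0, 2000.0)

#: Per-synapse work metrics compared across levels. ``sum`` and
#: ``sum_sq`` are per-afferent means (fan-in-normalised aggregates);
#: ``max`` is already a per-synapse quantity; ``rate`` is the first
#: difference of cumulative per-synapse work, identical to ``sum`` on
#: the unit iteration grid.
METRIC_MEASURES = {"sum": "entropy_gen", "sum_sq": "delta_sq", "max": "delta_max",
                   "rate": "entropy_gen"}


@dataclass
class SweepResult:
    """Outcome table of one sweep plus the manifest needed to re-run it.

    ``table`` has one row per parameter combination. ``meta`` records
    axis values, seeds, and replicate counts; ``extras`` holds sweep-
    specific derived tables (e.g. factorial marginal means).
    """

    name: str
    table: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)
    extras: Dict[str, object] = field(default_factory=dict)


def _fan_in(config: NetworkConfig) -> np.ndarray:
    return np.array([1.0, 1.0, float(config.nodes_per_level)])


def _metric_auc(summary: EnsembleSummary, metric: str, config: NetworkConfig) -> np.ndarray:
    """(n_trials, 3) per-trial AUC of a per-synapse work metric."""
    measure = METRIC_MEASURES[metric]
    v = summary.trial_auc[measure]
    if metric in ("sum_sq", "max"):
        # delta_sq is a raw per-afferent sum; normalise. delta_max is not.
        if metric == "sum_sq":
            v = v / _fan_in(config)[None, :]
    return v


def _elevation_row(auc_trials: np.ndarray) -> dict:
    """Level 3 vs Level 1 elevation with paired t statistics, NaN-flagged
    when the reference burden is exactly zero (no learning)."""
    mean = auc_trials.mean(axis=0)
    if mean[0] == 0.0:
        return {"auc_l1": 0.0, "auc_l2": mean[1], "auc_l3": mean[2],
                "elevation_pct": float("nan"), "t": float("nan"),
                "p": float("nan"), "defined": False}
    t, p = compare_levels(auc_trials[:, 2], auc_trials[:, 0], paired=True)
    return {"auc_l1": mean[0], "auc_l2": mean[1], "auc_l3": mean[2],
            "elevation_pct": percent_elevation(mean[2], mean[0]),
            "t": t, "p": p, "defined": True}


def metric_sweep(
    config: NetworkConfig,
    stimulus: StimulusConfig,
    n_trials: int,
    base_seed: int,
) -> SweepResult:
    """Evaluate all four work metrics in parallel on one ensemble.

    The same trial trajectories underlie every metric, so differences
    between rows reflect the accumulation rule alone.
    """
    summary = run_ensemble(config, stimulus, n_trials, base_seed)
    rows = []
    for metric in METRIC_MEASURES:
        row = {"metric": metric}
        row.update(_elevation_row(_metric_auc(summary, metric, config)))
        rows.append(row)
    return SweepResult(
        name="metric",
        table=pd.DataFrame(rows),
        meta={"n_trials": n_trials, "base_seed": base_seed,
              "regime": stimulus.regime},
        extras={"summary": summary},
    )


def input_regime_sweep(
    config: NetworkConfig,
    n_trials: int,
    base_seed: int,
    stimulus: Optional[StimulusConfig] = None,
) -> SweepResult:
    """Run one ensemble per input regime and compare work elevations.

    ``stimulus`` provides shared channel parameters; its regime field is
    overridden per row. Every regime uses the same base seed so weight
    initialisations are matched across rows.
    """
    base_stim = stimulus if stimulus is not None else StimulusConfig(
        n_channels=config.nodes_per_level
    )
    rows = []
    summaries = {}
    for regime in ("random", "correlated_gaussian", "sinusoidal"):
        summary = run_ensemble(
            config, base_stim.replace(regime=regime), n_trials, base_seed
        )
        summaries[regime] = summary
        row = {"regime": regime}
        row.update(_elevation_row(summary.trial_auc["entropy_gen"]))
        rows.append(row)
    return SweepResult(
        name="inputs",
        table=pd.DataFrame(rows),
        meta={"n_trials": n_trials, "base_seed": base_seed},
        extras={"summaries": summaries},
    )


def activation_sweep(
    config: NetworkConfig,
    stimulus: StimulusConfig,
    n_trials: int,
    base_seed: int,
) -> SweepResult:
    """Substitute the activation nonlinearity and compare work elevations."""
    rows = []
    for kind in ("tanh", "sigmoid", "relu", "linear"):
        summary = run_ensemble(
            config.replace(activation_kind=kind), stimulus, n_trials, base_seed
        )
        row = {"activation": kind}
        row.update(_elevation_row(summary.trial_auc["entropy_gen"]))
        rows.append(row)
    return SweepResult(
        name="activation",
        table=pd.DataFrame(rows),
        meta={"n_trials": n_trials, "base_seed": base_seed,
              "regime": stimulus.regime},
    )


def _failure_order(lead: Optional[float], tol: float = 1e-9) -> str:
    if lead is None:
        return "undetermined"
    if abs(lead) <= tol:
        return "tie"
    return "support_first" if lead > 0 else "cortex_first"


def _siphon_row(cfg: SiphonConfig) -> dict:
    ms = milestones(run_siphon(cfg))
    return {
        "t50_support": ms["t50_support"],
        "t50_cortex": ms["t50_cortex"],
        "lead_time": ms["lead_time"],
        "failure_order": _failure_order(ms["lead_time"]),
    }


def ffe_grid_sweep(
    cfg: SiphonConfig,
    cortex_grid: Sequence[float] = FFE_CORTEX_GRID,
    support_grid: Sequence[float] = FFE_SUPPORT_GRID,
) -> SweepResult:
    """Failure order and lead time over the full FFE parameter grid."""
    rows = []
    for fc, fs in itertools.product(cortex_grid, support_grid):
        row = {"ffe_cortex": fc, "ffe_support": fs,
               "ffe_differential": fc - fs}
        row.update(_siphon_row(cfg.replace(ffe_cortex=fc, ffe_support=fs)))
        rows.append(row)
    return SweepResult(
        name="ffe-grid",
        table=pd.DataFrame(rows),
        meta={"cortex_grid": list(cortex_grid), "support_grid": list(support_grid),
              "a_scale": cfg.a_scale, "dt": cfg.dt},
    )


def compensation_sweep(
    cfg: SiphonConfig, values: Sequence[float] = COMPENSATION_VALUES
) -> SweepResult:
    """Failure order and milestones across compensation-factor values."""
    rows = []
    for c in values:
        row = {"comp_factor": c}
        row.update(_siphon_row(cfg.replace(comp_factor=c)))
        rows.append(row)
    return SweepResult(
        name="compensation",
        table=pd.DataFrame(rows),
        meta={"values": list(values), "a_scale": cfg.a_scale},
    )


def _factorial_config(cfg: SiphonConfig, ratio: float, comp: float,
                      size: float) -> SiphonConfig:
    """One factorial cell: FFE_support anchored at 2.0, cortical FFE set
    by ratio, populations and workloads scaled so per-cell load is
    size-invariant (3.0 demand per cortical cell, baseline 500 at the
    reference size)."""
    scale = size / 1000.0
    return cfg.replace(
        ffe_support=2.0,
        ffe_cortex=2.0 * ratio,
        comp_factor=comp,
        n_cortex0=size,
        n_support0=0.3 * size,
        w_required=3.0 * size,
        w_baseline=500.0 * scale,
        horizon=max(cfg.horizon, 30.0),
    )


def factorial_interaction_sweep(
    cfg: SiphonConfig,
    ratios: Sequence[float] = FACTORIAL_FFE_RATIOS,
    comp_factors: Sequence[float] = FACTORIAL_COMP_FACTORS,
    sizes: Sequence[float] = FACTORIAL_SIZES,
) -> SweepResult:
    """Full factorial over FFE ratio x compensation x network size.

    ``extras`` carries marginal-mean main effects of lead time per
    factor and pairwise interaction (cell-mean) tables; the assessment
    is descriptive, not an ANOVA fit.
    """
    rows = []
    for r, c, s in itertools.product(ratios, comp_factors, sizes):
        row = {"ffe_ratio": r, "comp_factor": c, "size": s}
        row.update(_siphon_row(_factorial_config(cfg, r, c, s)))
        rows.append(row)
    table = pd.DataFrame(rows)
    factors = ("ffe_ratio", "comp_factor", "size")
    main_effects = {f: table.groupby(f)["lead_time"].mean() for f in factors}
    interactions = {
        (a, b): table.pivot_table(index=a, columns=b, values="lead_time",
                                  aggfunc="mean")
        for a, b in itertools.combinations(factors, 2)
    }
    effect_range = {f: float(v.max() - v.min()) for f, v in main_effects.items()}
    return SweepResult(
        name="factorial",
        table=table,
        meta={"ratios": list(ratios), "comp_factors": list(comp_factors),
              "sizes": list(sizes), "a_scale": cfg.a_scale},
        extras={"main_effects": main_effects, "interactions": interactions,
                "effect_range": effect_range},
    )
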