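"""Trial orchestration, summary statistics, and level comparisons.

An ensemble runs many independently seeded trials of the columnar
network and aggregates, per hierarchical level: the per-iteration
entropy-generation series (per-synapse work intensity of the tracked
node), cumulative work, normalised informational entropy, and the
Lyapunov stability estimate. Cross-level burden comparisons use the
per-trial trapezoidal area under the entropy-generation curve as the
paired unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import NetworkConfig, StimulusConfig
from .network import TrialTrace, run_trial

__all__ = [
    "EnsembleSummary",
    "run_ensemble",
    "auc",
    "percent_elevation",
    "compare_levels",
]

#: Measures collected per level; each maps to a (n_trials, 3, n_iter) array.
MEASURES = ("entropy_gen", "delta_sum", "delta_sq", "delta_max", "work_cum",
            "entropy_norm", "lyapunov")


def auc(series: np.ndarray) -> float:
    """Trapezoidal area under a per-iteration series on a unit grid."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    return float(np.trapezoid(s))


def percent_elevation(a: float, b: float) -> float:
    """Percent elevation of ``a`` over the reference ``b``: (a - b)/b * 100.

    Negative values indicate a gradient inversion (``a`` below the
    reference).
    """
    if b == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return (a - b) / b * 100.0


def compare_levels(
    x: np.ndarray, y: np.ndarray, paired: bool = True
) -> Tuple[float, float]:
    """Two-sided t-test between per-trial values of two levels.

    Paired comparisons (the within-architecture case) use a one-sample
    t-test on the differences; unpaired comparisons use Welch's t-test.
    Zero-variance degenerate inputs are flagged with a warning and
    reported as ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal lengths")
        d = x - y
        if np.ptp(d) == 0:
            if d[0] == 0:
                return 0.0, 1.0
            warnings.warn("zero-variance differences; t undefined", RuntimeWarning)
            return float("nan"), float("nan")
        res = stats.ttest_rel(x, y)
    else:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            warnings.warn("zero-variance samples; t undefined", RuntimeWarning)
            return float("nan"), float("nan")
        res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnsembleSummary:
    """Across-trial aggregates of a seeded ensemble.

    ``per_iteration`` holds, for each measure, across-trial mean and SD
    arrays of shape ``(3, n_iterations)``. ``trial_auc`` holds the
    per-trial AUC matrix ``(n_trials, 3)`` per measure, with
    ``auc_mean``/``auc_sd`` the across-trial moments. ``contrasts``
    holds paired t statistics between levels on the entropy-generation
    and Lyapunov AUCs.
    """

    config: NetworkConfig
    stimulus: StimulusConfig
    n_trials: int
    base_seed: int
    per_iteration: Dict[str, Dict[str, np.ndarray]]
    trial_auc: Dict[str, np.ndarray]
    auc_mean: Dict[str, np.ndarray]
    auc_sd: Dict[str, np.ndarray]
    contrasts: pd.DataFrame

    def elevation(self, measure: str = "entropy_gen",
                  level: int = 3, reference: int = 1) -> float:
        """Percent elevation of one level's mean AUC over another's."""
        m = self.auc_mean[measure]
        return percent_elevation(m[level - 1], m[reference - 1])

    def to_dict(self) -> dict:
        """JSON-serialisable summary (means, SDs, AUCs, contrasts)."""
        return {
            "n_trials": self.n_trials,
            "base_seed": self.base_seed,
            "per_iteration": {
                m: {k: v.tolist() for k, v in d.items()}
                for m, d in self.per_iteration.items()
            },
            "auc_mean": {m: v.tolist() for m, v in self.auc_mean.items()},
            "auc_sd": {m: v.tolist() for m, v in self.auc_sd.items()},
            "contrasts": self.contrasts.to_dict(orient="records"),
        }


def _collect(traces: List[TrialTrace]) -> Dict[str, np.ndarray]:
    return {m: np.stack([getattr(tr, m) for tr in traces]) for m in MEASURES}


def run_ensemble(
    config: NetworkConfig,
    stimulus: StimulusConfig,
    n_trials: int,
    base_seed: int,
) -> EnsembleSummary:
    """Run ``n_trials`` trials seeded ``base_seed + k`` and aggregate.

    Repeating with the same arguments reproduces the summary exactly.
    """
    if n_trials < 2:
        raise ValueError("need at least two trials")
    traces = [run_trial(config, stimulus, base_seed + k) for k in range(n_trials)]
    data = _collect(traces)

    per_iteration = {
        m: {"mean": a.mean(axis=0), "sd": a.std(axis=0, ddof=1)}
        for m, a in data.items()
    }
    trial_auc = {m: np.trapezoid(a, axis=2) for m, a in data.items()}
    auc_mean = {m: v.mean(axis=0) for m, v in trial_auc.items()}
    auc_sd = {m: v.std(axis=0, ddof=1) for m, v in trial_auc.items()}

    rows = []
    for measure in ("entropy_gen", "lyapunov"):
        v = trial_auc[measure]
        for a, b in ((3, 1), (3, 2), (2, 1)):
            t, p = compare_levels(v[:, a - 1], v[:, b - 1], paired=True)
            rows.append(
                {"measure": measure, "level_a": a, "level_b": b, "t": t, "p": p}
            )
    contrasts = pd.DataFrame(rows)

    return EnsembleSummary(
        config=config,
        stimulus=stimulus,
        n_trials=n_trials,
        base_seed=base_seed,
        per_iteration=per_iteration,
        trial_auc=trial_auc,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        contrasts=contrasts,
    )
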