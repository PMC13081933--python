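"""Coupled cortical/support population-failure model (the siphon effect).

A large cortical population must meet a constant cognitive demand. A
smaller support population provides baseline function plus compensation
proportional to cortical dysfunction,

    W_support = W_baseline + comp_factor * (N_lost / N_cortex0) * N_remaining,

and the compensation work it takes on offloads an equal amount of the
cortical demand (the siphon: workload migrates from the failing primary
population to its support system). Per-cell work intensity
``W / N_functional`` (capped at a physiological maximum) integrates
over time into an accumulated entropy index ``s``, and each
population's instantaneous failure rate follows the fatigue law

    N_failure = A * exp(s / FFE),

where FFE (fracture fatigue entropy) is the critical accumulated-entropy
threshold of that population. Integration is explicit Euler with
``dt = 0.1``; populations are real-valued and monotonically
non-increasing. The model is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import SiphonConfig

__all__ = [
    "SiphonState",
    "SiphonTrajectory",
    "support_work",
    "per_cell_intensity",
    "failure_rate",
    "tsi",
    "microstate_count",
    "step_siphon",
    "run_siphon",
    "milestones",
    "calibrate_a_scale",
    "REFERENCE_A_SCALE",
    "reference_config",
]

#: Division floor standing in for an empty population; intensity then
#: saturates at the cap rather than diverging.
POPULATION_FLOOR = 1e-9

#: Baseline failure-rate constant of the reference configuration, fitted
#: once by bisection (see :func:`calibrate_a_scale`) so that the support
#: population of the reference run crosses 50% loss at t = 5.5, and
#: frozen. Failure ordering and lead-time monotonicity are invariant to
#: this constant; only absolute milestone times depend on it.
REFERENCE_A_SCALE = 0.9002232226238583


def support_work(n_lost: float, n_remaining: float, cfg: SiphonConfig) -> float:
    """Support-population workload: baseline plus compensation.

    Compensation is proportional to the fraction of cortical cells lost
    times the number still there to support, so it peaks at intermediate
    cortical loss and vanishes again when nothing remains to support.
    """
    return cfg.w_baseline + cfg.comp_factor * (n_lost / cfg.n_cortex0) * n_remaining


def per_cell_intensity(total_work: float, n_functional: float, cap: float) -> float:
    """Work intensity per functional cell, saturated at the physiological cap."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return min(total_work / max(n_functional, POPULATION_FLOOR), cap)


def failure_rate(s: float, ffe: float, a_scale: float) -> float:
    """Instantaneous failure rate ``A * exp(s / FFE)`` in cells per time.

    Strictly increasing in the accumulated entropy ``s`` and decreasing
    in the resilience threshold ``FFE``; at ``s = 0`` it equals the
    baseline constant ``A``.
    """
    if ffe <= 0:
        raise ValueError("ffe must be positive")
    return a_scale * math.exp(s / ffe)


def tsi(s: float, ffe: float) -> float:
    """Thermodynamic State Index: degradation coordinate ``s / FFE``.

    Runs from 0 in the pristine state toward 1 at failure but is capped
    just below 1 (complete equilibrium is reached only asymptotically).
    """
    if ffe <= 0:
        raise ValueError("ffe must be positive")
    if s < 0:
        raise ValueError("accumulated entropy must be non-negative")
    return min(s / ffe, 1.0 - 1e-6)


def microstate_count(s: float, k: float) -> float:
    """Number of microstates ``w = exp(s / k)`` from the Boltzmann relation s = k ln w."""
    if k <= 0:
        raise ValueError("k must be positive")
    return math.exp(s / k)


@dataclass(frozen=True)
class SiphonState:
    """Instantaneous state of the coupled populations."""

    t: float
    n_cortex: float
    n_support: float
    s_cortex: float
    s_support: float
    intensity_cortex: float
    intensity_support: float
    rate_cortex: float
    rate_support: float

    def tsi_cortex(self, cfg: SiphonConfig) -> float:
        return tsi(self.s_cortex, cfg.ffe_cortex)

    def tsi_support(self, cfg: SiphonConfig) -> float:
        return tsi(self.s_support, cfg.ffe_support)


def _workloads(n_cortex: float, cfg: SiphonConfig) -> tuple:
    """Total workload of each population at the given cortical census.

    The support population's compensation counts toward the cognitive
    demand, so the cortical population carries the remainder
    ``max(W_required - W_support, 0)``.
    """
    lost = cfg.n_cortex0 - n_cortex
    w_sup = support_work(lost, n_cortex, cfg)
    w_cor = max(cfg.w_required - w_sup, 0.0)
    return w_cor, w_sup


def step_siphon(state: SiphonState, cfg: SiphonConfig) -> SiphonState:
    """One explicit-Euler step of the coupled failure dynamics.

    The departing state's per-cell intensities (evaluated at its own
    census, capped) accumulate into each population's entropy index;
    failure rates then follow the fatigue law at the updated entropy;
    populations decrement by ``rate * dt``, floored at zero; and the new
    state's intensities are re-evaluated at the new census. The realised
    loss can never exceed the cells present, so recorded rates are
    bounded by ``n / dt``.
    """
    s_cor = state.s_cortex + state.intensity_cortex * cfg.dt
    s_sup = state.s_support + state.intensity_support * cfg.dt
    r_cor = min(failure_rate(s_cor, cfg.ffe_cortex, cfg.a_scale), state.n_cortex / cfg.dt)
    r_sup = min(failure_rate(s_sup, cfg.ffe_support, cfg.a_scale), state.n_support / cfg.dt)
    n_cor = max(state.n_cortex - r_cor * cfg.dt, 0.0)
    n_sup = max(state.n_support - r_sup * cfg.dt, 0.0)
    w_cor, w_sup = _workloads(n_cor, cfg)
    return SiphonState(
        t=state.t + cfg.dt,
        n_cortex=n_cor,
        n_support=n_sup,
        s_cortex=s_cor,
        s_support=s_sup,
        intensity_cortex=per_cell_intensity(w_cor, n_cor, cfg.intensity_cap),
        intensity_support=per_cell_intensity(w_sup, n_sup, cfg.intensity_cap),
        rate_cortex=r_cor,
        rate_support=r_sup,
    )


@dataclass
class SiphonTrajectory:
    """Full time course of a siphon run plus its extracted milestones."""

    config: SiphonConfig
    states: List[SiphonState]

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {
                "t": [s.t for s in self.states],
                "n_cortex": [s.n_cortex for s in self.states],
                "n_support": [s.n_support for s in self.states],
                "intensity_cortex": [s.intensity_cortex for s in self.states],
                "intensity_support": [s.intensity_support for s in self.states],
                "s_cortex": [s.s_cortex for s in self.states],
                "s_support": [s.s_support for s in self.states],
                "rate_cortex": [s.rate_cortex for s in self.states],
                "rate_support": [s.rate_support for s in self.states],
                "tsi_cortex": [s.tsi_cortex(cfg) for s in self.states],
                "tsi_support": [s.tsi_support(cfg) for s in self.states],
            }
        )

    def milestones(self) -> Dict[str, Optional[float]]:
        return milestones(self)


def run_siphon(cfg: SiphonConfig) -> SiphonTrajectory:
    """Integrate the model over the horizon. Deterministic."""
    w_cor, w_sup = _workloads(cfg.n_cortex0, cfg)
    init = SiphonState(
        t=0.0,
        n_cortex=cfg.n_cortex0,
        n_support=cfg.n_support0,
        s_cortex=0.0,
        s_support=0.0,
        intensity_cortex=per_cell_intensity(w_cor, cfg.n_cortex0, cfg.intensity_cap),
        intensity_support=per_cell_intensity(w_sup, cfg.n_support0, cfg.intensity_cap),
        rate_cortex=failure_rate(0.0, cfg.ffe_cortex, cfg.a_scale),
        rate_support=failure_rate(0.0, cfg.ffe_support, cfg.a_scale),
    )
    states = [init]
    n_steps = int(round(cfg.horizon / cfg.dt))
    for _ in range(n_steps):
        states.append(step_siphon(states[-1], cfg))
    return SiphonTrajectory(config=cfg, states=states)


def _first_crossing(ts: np.ndarray, values: np.ndarray, threshold: float) -> Optional[float]:
    """Time of first downward crossing, linearly interpolated between steps."""
    below = np.nonzero(values <= threshold)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(ts[0])
    frac = (values[i - 1] - threshold) / (values[i - 1] - values[i])
    return float(ts[i - 1] + frac * (ts[i] - ts[i - 1]))


def milestones(traj: SiphonTrajectory) -> Dict[str, Optional[float]]:
    """Landmark times of a trajectory.

    ``t50``/``t90`` are the first crossings of 50% and 90% population
    loss (linear interpolation between grid points; ``None`` if never
    crossed within the horizon). ``t_cap`` is the first time a
    population's per-cell intensity reaches the cap. Peak rates are the
    largest realised failure rates. ``lead_time`` is
    ``t50_cortex - t50_support``: positive when the support population
    fails first.
    """
    df = traj.to_frame()
    cfg = traj.config
    ts = df["t"].to_numpy()
    out: Dict[str, Optional[float]] = {}
    for pop, n0 in (("cortex", cfg.n_cortex0), ("support", cfg.n_support0)):
        n = df[f"n_{pop}"].to_numpy()
        out[f"t50_{pop}"] = _first_crossing(ts, n, 0.5 * n0)
        out[f"t90_{pop}"] = _first_crossing(ts, n, 0.1 * n0)
        intensity = df[f"intensity_{pop}"].to_numpy()
        at_cap = np.nonzero(intensity >= cfg.intensity_cap - 1e-12)[0]
        out[f"t_cap_{pop}"] = float(ts[at_cap[0]]) if at_cap.size else None
        rate = df[f"rate_{pop}"].to_numpy()
        j = int(np.argmax(rate))
        out[f"peak_rate_{pop}"] = float(rate[j])
        out[f"t_peak_rate_{pop}"] = float(ts[j])
    if out["t50_cortex"] is not None and out["t50_support"] is not None:
        out["lead_time"] = out["t50_cortex"] - out["t50_support"]
    else:
        out["lead_time"] = None
    return out


def calibrate_a_scale(
    cfg: SiphonConfig,
    target_t50_support: float = 5.5,
    lo: float = 1e-4,
    hi: float = 10.0,
    n_bisect: int = 60,
) -> float:
    """Fit the baseline failure-rate constant by bisection.

    Returns the ``a_scale`` for which the support population of ``cfg``
    first crosses 50% loss at ``target_t50_support``. The support t50 is
    strictly decreasing in ``a_scale``, so bisection on its logarithm
    converges; 60 halvings pin the constant to ~1e-5 relative precision.
    """
    def t50(a: float) -> Optional[float]:
        traj = run_siphon(cfg.replace(a_scale=a))
        return milestones(traj)["t50_support"]

    for _ in range(n_bisect):
        mid = math.sqrt(lo * hi)
        t = t50(mid)
        if t is None or t > target_t50_support:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def reference_config(**overrides) -> SiphonConfig:
    """The reference parameterisation with the frozen calibrated ``a_scale``."""
    base = dict(a_scale=REFERENCE_A_SCALE)
    base.update(overrides)
    return SiphonConfig(**base)
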