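"""The three-level convergent columnar Hebbian network.

Architecture (for ``m = nodes_per_level``): ``m`` primary (Level 1)
nodes, each with a single weight on its own external input channel;
``m`` unimodal (Level 2) nodes wired one-to-one to the primary nodes;
and ``m`` heteromodal (Level 3) nodes, each receiving input from all
unimodal nodes (fan-in ``m``). All weights are initialised uniformly
inside (0, 1) and updated with the rule ``dw_i = eta * (x_i - w_i)``,
which drives each weight exponentially toward its recent afferent
values.

Work accounting treats every weight modification as irreversible
mechanical work of magnitude ``|dw_i|``. Magnitudes are aggregated with
absolute values, never signed sums: opposing modifications at different
synapses both cost work, so their contributions add rather than cancel.
The entropy-generation increment attributed to a node is its work
intensity per synapse, ``sum_i |dw_i| / n_afferents``, mirroring the
per-cell work intensity that drives failure in the siphon model.

Dynamic stability is quantified by a discrete Lyapunov estimate: a
shadow copy of the network receives every external input shifted by
``+epsilon`` and learns alongside the main network; the exponent at
iteration ``t`` is the log ratio of successive activation divergences,
``lambda(t) = ln(d_t / d_{t-1})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, NetworkConfig, StimulusConfig
from .stimuli import stimulus_stream

__all__ = [
    "NetworkState",
    "TrialTrace",
    "activate",
    "build_architecture",
    "hebbian_update",
    "step_network",
    "forward_pass",
    "work_metrics",
    "shannon_entropy",
    "level_entropy",
    "lyapunov_step",
    "run_trial",
]

WORK_METRICS = ("sum", "sum_sq", "max", "rate")

_TINY = 1e-300  # divergence floor; ln(_TINY) stands in for -inf

_ACTIVATIONS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "relu": lambda z: np.maximum(z, 0.0),
    "linear": lambda z: np.asarray(z, dtype=float),
}


def activate(weights: np.ndarray, inputs: np.ndarray, kind: str = "tanh") -> float:
    """Node activation: nonlinearity applied to the weighted input sum.

    ``tanh`` bounds the output to (-1, 1) and ``sigmoid`` to (0, 1);
    ``relu`` and ``linear`` are unbounded.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"weights {w.shape} and inputs {x.shape} differ in length")
    try:
        f = _ACTIVATIONS[kind]
    except KeyError:
        raise ConfigurationError(f"unknown activation kind {kind!r}") from None
    return float(f(np.dot(w, x)))


def hebbian_update(
    weights: np.ndarray, inputs: np.ndarray, eta: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Move each weight a fraction ``eta`` toward its afferent value.

    Returns the updated weights and the absolute modification magnitudes
    ``|dw_i| = eta * |x_i - w_i|``. The fixed point of the rule is
    ``w = x``; under a constant input the gap ``|w - x|`` shrinks by the
    factor ``(1 - eta)`` per application.
    """
    if not (0.0 <= eta <= 1.0):
        raise ConfigurationError(f"eta must lie in [0, 1], got {eta}")
    w = np.asarray(weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"weights {w.shape} and inputs {x.shape} differ in length")
    delta = eta * (x - w)
    return w + delta, np.abs(delta)


@dataclass
class NetworkState:
    """Weights and wiring of the convergent column.

    ``w1`` and ``w2`` hold one weight per node (fan-in 1); ``w3`` is an
    ``(m, m)`` matrix whose row ``j`` holds heteromodal node ``j``'s
    weights on all unimodal activations.
    """

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    activation_kind: str = "tanh"

    @property
    def nodes_per_level(self) -> int:
        return self.w1.shape[0]

    @property
    def fan_in(self) -> Tuple[int, int, int]:
        """Afferents per node at each level."""
        return (1, 1, self.w3.shape[1])

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.w1.copy(), self.w2.copy(), self.w3.copy(), self.activation_kind
        )


def build_architecture(config: NetworkConfig, rng: np.random.Generator) -> NetworkState:
    """Wire the column and draw every weight uniformly from the init range."""
    m = config.nodes_per_level
    lo, hi = config.weight_init_range
    return NetworkState(
        w1=rng.uniform(lo, hi, m),
        w2=rng.uniform(lo, hi, m),
        w3=rng.uniform(lo, hi, (m, m)),
        activation_kind=config.activation_kind,
    )


def forward_pass(state: NetworkState, external_inputs: np.ndarray) -> List[np.ndarray]:
    """Bottom-up activations ``[y1, y2, y3]`` for one stimulus vector."""
    x = np.asarray(external_inputs, dtype=float)
    if x.shape != state.w1.shape:
        raise ValueError(
            f"expected {state.w1.shape[0]} external inputs, got {x.shape}"
        )
    f = _ACTIVATIONS[state.activation_kind]
    y1 = f(state.w1 * x)
    y2 = f(state.w2 * y1)
    y3 = f(state.w3 @ y2)
    return [y1, y2, y3]


def step_network(
    state: NetworkState, external_inputs: np.ndarray, config: NetworkConfig
) -> Tuple[NetworkState, List[np.ndarray]]:
    """One learning step: forward pass, then a Hebbian update at every node.

    Each node's update uses its afferent values from this iteration's
    (pre-update) forward pass: the external input for Level 1 and the
    presynaptic activations for Levels 2 and 3. Returns the new state
    and the per-level absolute modification magnitudes (``(m,)`` for
    Levels 1-2 and ``(m, m)`` for Level 3).
    """
    x = np.asarray(external_inputs, dtype=float)
    y1, y2, _ = forward_pass(state, x)
    eta = config.eta
    new_w1, d1 = hebbian_update(state.w1, x, eta)
    new_w2, d2 = hebbian_update(state.w2, y1, eta)
    new_w3, d3 = hebbian_update(state.w3, np.broadcast_to(y2, state.w3.shape), eta)
    new_state = NetworkState(new_w1, new_w2, new_w3, state.activation_kind)
    return new_state, [d1, d2, d3]


def work_metrics(deltas_per_iteration: Sequence[Sequence[float]], metric: str) -> np.ndarray:
    """Aggregate per-iteration weight-change magnitudes into a work series.

    ``sum`` adds the magnitudes (the primary, thermodynamically additive
    metric), ``sum_sq`` adds their squares, ``max`` takes the largest
    single modification, and ``rate`` is the first difference of the
    cumulative sum series (identical to ``sum`` on a unit iteration
    grid, retained as an explicit rate-of-change reading).
    """
    if metric not in WORK_METRICS:
        raise ConfigurationError(f"unknown work metric {metric!r}; choose from {WORK_METRICS}")
    if len(deltas_per_iteration) == 0:
        raise ValueError("need at least one iteration of deltas")
    per_iter = []
    for deltas in deltas_per_iteration:
        a = np.abs(np.asarray(deltas, dtype=float)).ravel()
        if a.size == 0:
            per_iter.append((0.0, 0.0, 0.0))
        else:
            per_iter.append((a.sum(), (a**2).sum(), a.max()))
    sums, sq, mx = (np.array(v) for v in zip(*per_iter))
    if metric == "sum":
        return sums
    if metric == "sum_sq":
        return sq
    if metric == "max":
        return mx
    return np.diff(np.cumsum(sums), prepend=0.0)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy ``H = -sum p_i log2 p_i`` in bits, with 0*log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"probabilities must sum to 1, got {total}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def level_entropy(activations: np.ndarray) -> float:
    """Normalised Shannon entropy of a level's activation-magnitude pattern.

    Activation magnitudes are normalised into a probability vector
    (uniform if all activations are zero) and the entropy is divided by
    ``log2(n)``, so the result lies in [0, 1] and equals 1 exactly when
    all activations have equal magnitude.
    """
    y = np.abs(np.asarray(activations, dtype=float))
    n = y.size
    if n < 2:
        raise ValueError("need at least two activations")
    total = y.sum()
    p = np.full(n, 1.0 / n) if total == 0 else y / total
    return shannon_entropy(p) / np.log2(n)


def _level_divergence(
    state_a: NetworkState, state_b: NetworkState, x: np.ndarray, epsilon: float
) -> np.ndarray:
    """Euclidean distance per level between activations of ``state_a`` on
    ``x`` and ``state_b`` on ``x + epsilon`` (added to every channel)."""
    ya = forward_pass(state_a, x)
    yb = forward_pass(state_b, np.asarray(x, dtype=float) + epsilon)
    return np.array(
        [max(float(np.linalg.norm(a - b)), _TINY) for a, b in zip(ya, yb)]
    )


def lyapunov_step(
    state: NetworkState, external_inputs: np.ndarray, epsilon: float
) -> np.ndarray:
    """Single-pass log amplification of an input perturbation, per level.

    Runs one forward pass with ``external_inputs`` and one with every
    channel shifted by ``+epsilon`` (same weights) and returns
    ``ln(d / (epsilon * sqrt(n)))`` per level, where ``d`` is the
    Euclidean distance between the two activation vectors at that level
    and ``n`` the number of perturbed channels. For a linear one-weight
    chain of gain ``g`` this reduces to ``ln g``. Zero divergence is
    floored at machine-tiny and reported as a large negative exponent.
    """
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    x = np.asarray(external_inputs, dtype=float)
    d = _level_divergence(state, state, x, epsilon)
    return np.log(d / (epsilon * np.sqrt(x.size)))


@dataclass
class TrialTrace:
    """Per-iteration measurements of the tracked node at each level.

    All arrays have shape ``(3, n_iterations)`` (level by iteration).
    ``delta_sum``/``delta_sq``/``delta_max`` aggregate the tracked
    node's weight-change magnitudes per the corresponding work metric;
    ``work_cum`` is the running total of ``delta_sum``; ``entropy_gen``
    is the per-synapse entropy-generation increment (``delta_sum``
    divided by the node's fan-in); ``entropy_norm`` is the normalised
    informational entropy of the level's activation pattern; and
    ``lyapunov`` is the trajectory-divergence stability estimate.
    """

    seed: int
    delta_sum: np.ndarray
    delta_sq: np.ndarray
    delta_max: np.ndarray
    work_cum: np.ndarray
    entropy_gen: np.ndarray
    entropy_norm: np.ndarray
    lyapunov: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.delta_sum.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per level and iteration."""
        rows = []
        for level in range(3):
            for t in range(self.n_iterations):
                rows.append(
                    {
                        "trial_id": self.seed,
                        "level": level + 1,
                        "iteration": t + 1,
                        "delta_sum": self.delta_sum[level, t],
                        "delta_sq": self.delta_sq[level, t],
                        "delta_max": self.delta_max[level, t],
                        "work_cum": self.work_cum[level, t],
                        "entropy_norm": self.entropy_norm[level, t],
                        "lyapunov": self.lyapunov[level, t],
                    }
                )
        return pd.DataFrame(rows)


def _tracked_deltas(deltas: List[np.ndarray], index: int) -> List[np.ndarray]:
    """The tracked node's modification magnitudes at each level."""
    return [
        np.atleast_1d(deltas[0][index]),
        np.atleast_1d(deltas[1][index]),
        np.asarray(deltas[2][index]).ravel(),
    ]


def run_trial(
    config: NetworkConfig, stimulus: StimulusConfig, seed: int
) -> TrialTrace:
    """Run one seeded learning trial and record the tracked-node trace.

    The stimulus stream and initial weights are drawn from a generator
    seeded with ``seed``, so identical seeds give bit-identical traces.
    A shadow network receiving every input shifted by ``+epsilon``
    learns alongside the main network; Lyapunov exponents are log ratios
    of successive post-update activation divergences, with the initial
    divergence taken from the untrained pair on the first stimulus.
    """
    rng = np.random.default_rng(seed)
    state = build_architecture(config, rng)
    shadow = state.copy()
    stimuli = stimulus_stream(stimulus, rng, config.n_iterations)
    eps = config.lyapunov_epsilon
    idx = config.tracked_node_index
    fan_in = np.array(state.fan_in, dtype=float)

    n_iter = config.n_iterations
    shape = (3, n_iter)
    d_sum = np.zeros(shape)
    d_sq = np.zeros(shape)
    d_max = np.zeros(shape)
    h_norm = np.zeros(shape)
    lam = np.zeros(shape)

    d_prev = _level_divergence(state, shadow, stimuli[0], eps)
    for t in range(n_iter):
        x = stimuli[t]
        activations = forward_pass(state, x)
        for level in range(3):
            h_norm[level, t] = level_entropy(activations[level])
        state, deltas = step_network(state, x, config)
        shadow, _ = step_network(shadow, x + eps, config)
        tracked = _tracked_deltas(deltas, idx)
        for level, a in enumerate(tracked):
            d_sum[level, t] = a.sum()
            d_sq[level, t] = (a**2).sum()
            d_max[level, t] = a.max()
        d_now = _level_divergence(state, shadow, x, eps)
        lam[:, t] = np.log(d_now / d_prev)
        d_prev = d_now

    return TrialTrace(
        seed=seed,
        delta_sum=d_sum,
        delta_sq=d_sq,
        delta_max=d_max,
        work_cum=np.cumsum(d_sum, axis=1),
        entropy_gen=d_sum / fan_in[:, None],
        entropy_norm=h_norm,
        lyapunov=lam,
    )
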