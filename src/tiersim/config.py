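"""Configuration objects for the network, stimulus, and siphon models.

All parameters are dimensionless indices: synaptic work is an abstract
work-per-modification index, and the siphon model's "work units" and
"time units" are not calibrated to biological measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

ACTIVATION_KINDS = ("tanh", "sigmoid", "relu", "linear")
STIMULUS_REGIMES = ("random", "correlated_gaussian", "sinusoidal")


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture, learning, and tracking parameters for the hierarchical network.

    The network is a three-level convergent column: ``nodes_per_level``
    primary nodes each receiving one external input channel, the same
    number of unimodal nodes wired one-to-one to the primary nodes, and
    the same number of heteromodal nodes each receiving input from every
    unimodal node.

    Parameters
    ----------
    eta : float
        Hebbian learning rate in (0, 1]. Each weight moves a fraction
        ``eta`` of the way toward its afferent value per iteration.
    weight_init_range : (float, float)
        Uniform initialisation interval for all weights, inside (0, 1)
        to avoid activation saturation.
    activation_kind : str
        One of ``tanh`` (default), ``sigmoid``, ``relu``, ``linear``.
    n_iterations : int
        Learning iterations per trial.
    tracked_node_index : int
        Index of the representative node tracked at each level.
    lyapunov_epsilon : float
        Magnitude of the input perturbation used for the dynamic
        stability (Lyapunov) estimate.
    """

    n_levels: int = 3
    nodes_per_level: int = 4
    eta: float = 0.1
    weight_init_range: Tuple[float, float] = (0.1, 0.9)
    activation_kind: str = "tanh"
    n_iterations: int = 20
    tracked_node_index: int = 0
    lyapunov_epsilon: float = 0.001

    def __post_init__(self) -> None:
        if self.n_levels != 3:
            raise ConfigurationError("the convergent column has exactly 3 levels")
        if self.nodes_per_level < 1:
            raise ConfigurationError("nodes_per_level must be >= 1")
        if not (0.0 <= self.eta <= 1.0):
            # eta = 0 is allowed as a degenerate no-learning control
            raise ConfigurationError(f"eta must lie in [0, 1], got {self.eta}")
        lo, hi = self.weight_init_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"weight_init_range must lie within (0, 1), got {self.weight_init_range}"
            )
        if self.activation_kind not in ACTIVATION_KINDS:
            raise ConfigurationError(
                f"unknown activation {self.activation_kind!r}; choose from {ACTIVATION_KINDS}"
            )
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not (0 <= self.tracked_node_index < self.nodes_per_level):
            raise ConfigurationError("tracked_node_index must be < nodes_per_level")
        if self.lyapunov_epsilon <= 0:
            raise ConfigurationError("lyapunov_epsilon must be positive")

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the three input regimes.

    ``random``: independent uniform draws on ``[base - half_range,
    base + half_range]`` plus bounded uniform noise of half-width
    ``noise_halfwidth``, redrawn every iteration.

    ``correlated_gaussian``: equicorrelated Gaussians with mean ``base``,
    standard deviation ``gaussian_sd`` and pairwise correlation ``rho``,
    clipped to [0, 1].

    ``sinusoidal``: deterministic ``base + 0.4 * sin(2*pi*f_i*t + phi_i)``
    with a distinct frequency per channel.
    """

    regime: str = "random"
    n_channels: int = 4
    base: float = 0.5
    half_range: float = 0.1
    noise_halfwidth: float = 0.05
    rho: float = 0.3
    gaussian_sd: float = 0.05
    sin_amplitude: float = 0.4
    freqs: Optional[Tuple[float, ...]] = None
    phases: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.regime not in STIMULUS_REGIMES:
            raise ConfigurationError(
                f"unknown stimulus regime {self.regime!r}; choose from {STIMULUS_REGIMES}"
            )
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigurationError(f"rho must lie in [0, 1), got {self.rho}")
        if self.gaussian_sd <= 0:
            raise ConfigurationError("gaussian_sd must be positive")
        if self.freqs is not None and len(self.freqs) != self.n_channels:
            raise ConfigurationError("freqs must have one entry per channel")
        if self.phases is not None and len(self.phases) != self.n_channels:
            raise ConfigurationError("phases must have one entry per channel")
        if self.regime == "sinusoidal":
            f = self.effective_freqs()
            if len(set(f)) != len(f):
                raise ConfigurationError("sinusoidal regime requires distinct frequencies")

    def effective_freqs(self) -> Tuple[float, ...]:
        """Per-channel frequencies; defaults to 1..n cycles per 20 iterations."""
        if self.freqs is not None:
            return tuple(self.freqs)
        return tuple((k + 1) / 20.0 for k in range(self.n_channels))

    def effective_phases(self) -> Tuple[float, ...]:
        if self.phases is not None:
            return tuple(self.phases)
        return tuple(0.0 for _ in range(self.n_channels))

    def replace(self, **changes) -> "StimulusConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SiphonConfig:
    """Parameters of the coupled cortical/support population-failure model.

    The cortical population must meet a constant cognitive demand
    ``w_required``. The support population provides ``w_baseline`` plus
    compensation proportional to cortical dysfunction; the compensation
    work offloads an equal amount of cortical demand (the siphon).
    Per-cell work intensity is capped at ``intensity_cap`` and integrates
    into an accumulated entropy index ``s``; the instantaneous failure
    rate is ``a_scale * exp(s / FFE)`` cells per time unit.
    """

    n_cortex0: float = 1000.0
    n_support0: float = 300.0
    c_per_cell: float = 1.0
    w_required: float = 3000.0
    w_baseline: float = 500.0
    comp_factor: float = 2.0
    ffe_cortex: float = 6.0
    ffe_support: float = 2.0
    a_scale: float = 1.0
    dt: float = 0.1
    horizon: float = 20.0
    intensity_cap: float = 5.0

    def __post_init__(self) -> None:
        positive = (
            "n_cortex0", "n_support0", "c_per_cell", "w_required", "w_baseline",
            "ffe_cortex", "ffe_support", "a_scale", "dt", "horizon", "intensity_cap",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.comp_factor < 0:
            raise ConfigurationError("comp_factor must be non-negative")
        if self.dt > 0.1 + 1e-12:
            raise ConfigurationError("dt must be <= 0.1 so milestones resolve to one decimal")

    def replace(self, **changes) -> "SiphonConfig":
        return dataclasses.replace(self, **changes)
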