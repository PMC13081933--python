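"""Seeded stimulus generators for the three input regimes.

The random regime is the baseline used in the main ensemble; the
correlated-Gaussian and sinusoidal regimes are the structured-input
alternatives used in the sensitivity analysis. Stochastic regimes draw
from a caller-supplied :class:`numpy.random.Generator`; the sinusoidal
regime is a deterministic function of the iteration index.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, StimulusConfig


def random_inputs(cfg: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform draws on [base - half_range, base + half_range] plus bounded noise.

    With defaults this is U[0.4, 0.6] + U[-0.05, +0.05] per channel,
    independent across channels and iterations, so every value lies in
    [0.35, 0.65].
    """
    n = cfg.n_channels
    x = rng.uniform(cfg.base - cfg.half_range, cfg.base + cfg.half_range, n)
    x = x + rng.uniform(-cfg.noise_halfwidth, cfg.noise_halfwidth, n)
    return x


def equicorrelation_cholesky(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of the n x n equicorrelation matrix with off-diagonal rho."""
    c = np.full((n, n), rho, dtype=float)
    np.fill_diagonal(c, 1.0)
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:  # rho outside [0, 1) for this n
        raise ConfigurationError(
            f"equicorrelation matrix (n={n}, rho={rho}) is not positive definite"
        ) from exc


def correlated_gaussian_inputs(cfg: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """Equicorrelated Gaussian channels, mean ``base``, clipped to [0, 1].

    Channels share pairwise correlation ``cfg.rho`` (via the Cholesky
    factor of the equicorrelation matrix) and have marginal standard
    deviation ``cfg.gaussian_sd``. Tail mass outside [0, 1] is clipped;
    at the default sd of 0.05 around 0.5 that mass is negligible.
    """
    chol = equicorrelation_cholesky(cfg.n_channels, cfg.rho)
    z = chol @ rng.standard_normal(cfg.n_channels)
    return np.clip(cfg.base + cfg.gaussian_sd * z, 0.0, 1.0)


def sinusoidal_inputs(cfg: StimulusConfig, t: int) -> np.ndarray:
    """Deterministic sinusoidal channels ``base + A*sin(2*pi*f_i*t + phi_i)``.

    ``t`` is the 1-based iteration index. Default frequencies are
    {1, 2, 3, 4}/20 cycles per iteration so each channel completes one
    to four full cycles within a 20-iteration trial.
    """
    f = np.asarray(cfg.effective_freqs())
    phi = np.asarray(cfg.effective_phases())
    return cfg.base + cfg.sin_amplitude * np.sin(2.0 * np.pi * f * t + phi)


def stimulus_stream(cfg: StimulusConfig, rng: np.random.Generator, n_iterations: int) -> np.ndarray:
    """Stimuli for a whole trial, shape ``(n_iterations, n_channels)``.

    Iterations are numbered from 1 for the sinusoidal regime.
    """
    if cfg.regime == "random":
        return np.stack([random_inputs(cfg, rng) for _ in range(n_iterations)])
    if cfg.regime == "correlated_gaussian":
        return np.stack([correlated_gaussian_inputs(cfg, rng) for _ in range(n_iterations)])
    return np.stack([sinusoidal_inputs(cfg, t) for t in range(1, n_iterations + 1)])
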