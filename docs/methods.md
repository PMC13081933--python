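# Methods

`tiersim` implements two coupled views of the same physical idea: every
act of information processing is mechanical work, no work is perfectly
efficient, and the inefficiency accumulates as irreversible
thermodynamic entropy until a structure reaches its failure threshold.
The package contains (i) a three-level convergent Hebbian column that
measures where in a processing hierarchy that work is concentrated, and
(ii) a deterministic two-population failure model (the "siphon" model)
that follows accumulated entropy through to structural collapse.

## The convergent column

**Architecture.** Three levels of four nodes. Primary (Level 1) nodes
each read one external input channel through a single weight; unimodal
(Level 2) nodes are wired one-to-one to the primary nodes; heteromodal
(Level 3) nodes each receive all four unimodal activations (fan-in 4).
The one-to-one middle layer keeps hierarchical depth and architectural
convergence separable: only the top level integrates across streams.

**Dynamics.** All nodes apply an activation (tanh by default; sigmoid,
ReLU and linear are sweep alternatives) to the weighted sum of their
afferents. After each bottom-up pass, every weight moves toward its
afferent value, `Δw_i = η (x_i − w_i)` with `η = 0.1`, using the
pre-update activations of the lower level as afferent values. The rule
has its fixed point at `w = x` and contracts the gap by `(1 − η)` per
step under a constant input — the closed form the property tests check.
Weights start uniform on [0.1, 0.9]; because each update is a convex
combination of weight and afferent, no clipping is ever needed. A trial
is 20 iterations; ensembles repeat trials under seeds `base_seed + k`.

**Work accounting.** Each modification costs work `|Δw_i|`, and costs
at different synapses add — magnitudes are never allowed to cancel the
way signed sums would. The per-node *entropy-generation increment* is
the per-synapse work intensity

    Δs(t) = Σ_i |Δw_i(t)| / n_afferents ,

i.e. damage-relevant load is defined per constituent unit (per synapse
here, per cell in the siphon model), in the same way stress is defined
at a material point rather than for a whole beam. Raw sums
(`delta_sum`, `delta_sq`, `delta_max` in the trace tables) are kept
alongside, and the sensitivity sweep evaluates four accumulation rules
in parallel: per-synapse mean `|Δw|`, mean `Δw²`, max `|Δw|`, and the
rate form (first difference of cumulative work, identical to the mean
on a unit iteration grid). Cross-level comparisons use the trapezoidal
area under the 20-iteration `Δs` curve per trial, with paired t-tests
across trials and elevations reported as `(AUC_L3 − AUC_L1)/AUC_L1`.

**Informational entropy.** Per level and iteration, activation
magnitudes are normalised into a probability vector (uniform when all
activations are zero) and their Shannon entropy is divided by
`log2(n)`, giving a [0, 1] index that is 1 exactly for equal-magnitude
patterns. Informational entropy is kept strictly distinct from the
thermodynamic entropy index `s`.

**Dynamic stability.** A shadow copy of the network receives every
external input shifted by `+ε` (`ε = 0.001`) and learns alongside the
main network. After each update the Euclidean distance `d_t` between
the two activation vectors at a level is measured on the iteration's
stimulus, and the Lyapunov estimate is the one-step log divergence
ratio `λ(t) = ln(d_t / d_{t−1})`, with `d_0` taken from the untrained
pair on the first stimulus. Because the perturbation is persistent, the
weight trajectories themselves separate while learning is active and
re-converge as updates shrink, so λ starts small and positive
(~0.09–0.10) and decays toward zero — a direct readout of how much
ongoing synaptic adjustment the architecture needs to hold its
representation steady. A single-pass amplification form,
`ln(d / (ε√n))` at fixed weights, is exposed as `lyapunov_step` and
validated against the `ln(gain)` closed form for linear chains; it
measures instantaneous gain rather than learning-trajectory divergence.

**Stimuli.** Three regimes, all in [0, 1]: (a) random — independent
U[0.4, 0.6] plus bounded uniform noise U[−0.05, 0.05], redrawn every
iteration (the ± bracket reads as a bounded, not Gaussian,
perturbation); (b) correlated Gaussian — mean 0.5, sd 0.05 (chosen to
match the random regime's spread), pairwise correlation ρ = 0.3 via the
Cholesky factor of the equicorrelation matrix, clipped to [0, 1]
(clipping rather than resampling: at sd 0.05 the clipped mass is
negligible); (c) sinusoidal — `0.5 + 0.4 sin(2π f_i t + φ_i)` with
default frequencies {1,2,3,4}/20 cycles per iteration and zero phases,
so each channel completes one to four cycles per trial.

## The siphon model

Two real-valued populations: 1000 cortical cells facing a constant
cognitive demand of 3000 work units per time unit, and 300 support
cells providing a 500-unit baseline plus compensation

    W_support = W_baseline + comp_factor · (N_lost / N_cortex0) · N_remaining ,

which peaks at intermediate cortical loss. The compensation work
*transfers* demand: the cortical population carries
`max(W_required − W_support, 0)`. This is the siphon itself — workload
migrating from the failing primary population onto its support system —
and it is what makes the support population fail first in every corner
of the FFE grid, including the equal-threshold corner where separate
work ledgers would let the harder-loaded cortical population fail
first.

Per-cell intensity `W / N_functional` is capped at 5.0 (the
physiological maximum) and integrates into each population's entropy
index `s`. Failure follows the fatigue law `N_failure = A·exp(s/FFE)`
cells per time unit, with `FFE_cortex = 6.0`, `FFE_support = 2.0` in
the reference run. The Thermodynamic State Index `s/FFE` is reported
capped just below 1. Integration is explicit Euler at `dt = 0.1`
(matching the one-decimal milestone resolution; intensities are
evaluated at the departing census, rates at the end-of-step entropy),
populations are continuous and floored at zero, and an empty
population's intensity saturates at the cap through a 1e-9 division
floor. Milestones (t50, t90, cap-hit times, peak realised rates, lead
time = t50_cortex − t50_support) are extracted with linear
interpolation between grid points.

The baseline constant `A` sets the absolute time scale only; failure
*order* and lead-time monotonicity are invariant to it. It is
calibrated once by bisection so the reference support population
crosses 50% loss at t = 5.5, then frozen
(`REFERENCE_A_SCALE ≈ 0.9002`) and recorded in every run manifest.

## Sensitivity analyses

Six prespecified sweeps: work metric (four rules on one set of
trajectories), input regime, activation function, the 6 × 5 FFE grid
(cortex {3..8} × support {1..3}), compensation factor
{0.5..4.0}, and a 3³ factorial over FFE ratio {2,3,4} (support
anchored at 2.0), compensation {1,2,3} and network size {500, 1000,
2000} cortical cells. Factorial cells scale the support population as
0.3× the cortical size and scale both demand (3.0 per cortical cell)
and baseline (0.5 per support cell) so per-cell load is
size-invariant — otherwise size changes would conflate with load
changes. Interaction assessment is descriptive (marginal means and
pairwise cell-mean tables), not an ANOVA fit.

## What the generators do and do not emulate

The synthetic stimuli isolate architectural effects: they carry no
temporal or cross-channel structure to learn (random), minimal shared
structure (ρ = 0.3), or perfectly predictable structure (sinusoidal).
Passing tests therefore demonstrate consequences of convergent wiring
under these idealised input statistics, not behaviour under
naturalistic, hierarchically structured signals, and the siphon model's
cell counts, work units and thresholds are deliberately uncalibrated to
biology — results are orderings, lead times and sensitivity patterns,
not biological time predictions.

## Numerical choices and edge cases

Entropy uses base-2 logarithms (bits); Lyapunov estimates use natural
logarithms (nats/step). `0·log 0 := 0`; probability vectors must be
non-negative and sum to 1 within 1e-8. Zero activation patterns fall
back to the uniform distribution. Divergences are floored at 1e-300
before taking logs. Zero-variance t-test inputs are flagged with a
warning and returned as NaN rather than raising mid-ensemble. η = 0 is
accepted as a degenerate no-learning control; elevation is then
undefined and flagged, not fabricated. Ensembles of fewer than two
trials are rejected.

## Default problem sizes

Trials run 20 iterations; full-scale ensembles use 2000 trials (the
acceptance script's scale, a few seconds per ensemble), while the test
suite uses 120–400-trial ensembles, which keep across-trial means of
every reported quantity stable to well within the assertion tolerances.
The siphon model always runs at full scale (it is deterministic and
takes milliseconds).

## Known limitations

- The work scale is a dimensionless index; only ratios, orderings and
  percent elevations are comparable across accounting conventions.
- The trajectory-divergence λ mixes stimulus-to-stimulus variability
  into individual per-trial series (the ensemble mean is unaffected);
  its first-iteration value depends on the `d_0` convention.
- With fan-in fixed at the top level, hierarchical position and
  convergence cannot be decomposed — Level 3's burden reflects both.
- The sigmoid variant centres activations near the mean initial weight,
  so its Level-3 per-synapse burden is slightly *below* Level 1's; the
  hierarchical elevation is robust across tanh/ReLU/linear but not
  sigmoid under this accounting.
- Euler integration at dt = 0.1 resolves milestones to ~0.1 time
  units; halving dt changes no ordering result.
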