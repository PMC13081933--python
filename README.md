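# tiersim

Simulation framework for the **thermodynamic-informational entropic
relationship (TIER)**: the hypothesis that information processing is
mechanical work, that the irreversible share of that work accumulates
as thermodynamic entropy (Δs ∝ W), and that a structure fails when its
accumulated entropy reaches an intrinsic threshold — its fracture
fatigue entropy (FFE). Applied to neural systems, this predicts that
the units doing the most integrative work, and the small support
populations that inherit workload from failing primary networks, are
the first to reach their thresholds.

The package is for computational and systems neuroscientists who want
to reproduce, probe, or extend these dynamics. It contains two models:

1. **Convergent Hebbian column** — a 4-4-4 feedforward hierarchy
   (primary → unimodal → heteromodal, with fan-in 4 only at the top).
   Each node applies `y = tanh(Σ wᵢ xᵢ)` and tracks weights toward
   afferents with `Δwᵢ = η (xᵢ − wᵢ)`, η = 0.1. Per node and iteration
   the simulator records the per-synapse work intensity
   `Δs(t) = Σ|Δwᵢ|/n_afferents`, the normalised Shannon entropy of the
   level's activation pattern `H = −Σ pᵢ log₂ pᵢ / log₂ n`, and a
   Lyapunov stability estimate `λ(t) = ln(d_t/d_{t−1})` from a shadow
   network driven by ε-perturbed inputs (ε = 0.001).

2. **Siphon model** — 1000 cortical cells under a constant cognitive
   demand (3000 units) coupled to 300 support cells providing
   `W_support = 500 + 2.0·(N_lost/1000)·N_remaining`; compensation work
   offloads cortical demand. Per-cell intensity (capped at 5.0)
   integrates into an entropy index `s`, and failures follow
   `N_failure = A·e^(s/FFE)` with FFE 6.0 (cortex) vs 2.0 (support).
   Deterministic explicit Euler, dt = 0.1.

Six prespecified sensitivity sweeps (work metric, input regime,
activation function, FFE grid, compensation factor, 3³ factorial) are
built in as library functions and CLI subcommands.

## Worked example

Reference siphon run (deterministic, < 1 s):

```
$ tiersim run-siphon --out siphon_out
t50 support: 5.50
t50 cortex: 12.80
wrote siphon_out/trajectory.csv, milestones.json, manifest.json
```

The support population — despite carrying less absolute work — crosses
50 % loss at t = 5.5, more than 7 time units before the cortical
population it sustains. The baseline failure constant A is calibrated
once so that the support t50 lands at 5.5 and is frozen in the manifest
(`a_scale ≈ 0.9002`); the failure *ordering* is invariant to A.

Smoke-scale network ensemble plus milestones (200 trials, seconds):

```
$ tiersim report --trials 200 --seed 1
Network level comparison (tracked node, per-synapse work):
  Level 1: work AUC 0.199 +/- 0.074
  Level 2: work AUC 0.247 +/- 0.147
  Level 3: work AUC 0.349 +/- 0.096
  Level 3 vs 1 elevation: +75.3%
```

Work AUC is the per-trial trapezoidal area under the 20-iteration
entropy-generation curve of the tracked node, averaged across trials:
the heteromodal level carries roughly 1.8× the per-synapse burden of
the primary level (paired t = 17.6, p ≈ 10⁻⁴²), the architectural
signature the framework predicts. Under sinusoidal (fully predictable)
inputs the gradient inverts — Level 3's burden drops *below* Level 1's
— while random and correlated-Gaussian inputs preserve it.

Other entry points: `tiersim run-network` (trace CSV + ensemble
summary JSON + manifest) and `tiersim sweep
{metric,inputs,ffe-grid,compensation,activation,factorial}`.

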