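"""Unit and property tests for the convergent columnar network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiersim import (
    ConfigurationError,
    NetworkConfig,
    StimulusConfig,
    activate,
    build_architecture,
    hebbian_update,
    level_entropy,
    lyapunov_step,
    run_trial,
    shannon_entropy,
    step_network,
    work_metrics,
)
from tiersim.network import NetworkState, forward_pass


class TestActivate:
    @pytest.mark.parametrize(
        "kind,expected", [("tanh", 0.0), ("relu", 0.0), ("linear", 0.0), ("sigmoid", 0.5)]
    )
    def test_zero_preactivation(self, kind, expected):
        assert activate([0.3, 0.7], [0.0, 0.0], kind) == pytest.approx(expected)

    def test_tanh_of_unit_preactivation(self):
        assert activate([1.0], [1.0], "tanh") == pytest.approx(0.76159, abs=1e-5)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_tanh_strictly_bounded(self, inputs):
        w = np.full(len(inputs), 0.9)
        assert abs(activate(w, inputs, "tanh")) < 1.0
        assert 0.0 < activate(w, inputs, "sigmoid") < 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            activate([1.0, 2.0], [1.0], "tanh")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            activate([1.0], [1.0], "softmax")


class TestHebbianUpdate:
    def test_fixed_point_at_input(self):
        w, d = hebbian_update([0.5], [0.5], eta=0.3)
        assert w[0] == pytest.approx(0.5)
        assert d[0] == 0.0

    def test_direct_evaluation(self):
        w, d = hebbian_update([0.1], [0.6], eta=0.1)
        assert d[0] == pytest.approx(0.05)
        assert w[0] == pytest.approx(0.15)

    def test_zero_learning_rate_is_inert(self):
        w0 = np.array([0.2, 0.8])
        w, d = hebbian_update(w0, [0.9, 0.1], eta=0.0)
        np.testing.assert_array_equal(w, w0)
        np.testing.assert_array_equal(d, [0.0, 0.0])

    @given(
        eta=st.floats(0.01, 1.0),
        w0=st.floats(0.0, 1.0),
        x=st.floats(0.0, 1.0),
        steps=st.integers(1, 30),
    )
    @settings(max_examples=60, derandomize=True)
    def test_constant_input_geometric_convergence(self, eta, w0, x, steps):
        """|w(t) - x| = (1 - eta)^t |w(0) - x| exactly under a constant input."""
        w = np.array([w0])
        for _ in range(steps):
            w, _ = hebbian_update(w, [x], eta)
        assert abs(w[0] - x) == pytest.approx(
            (1 - eta) ** steps * abs(w0 - x), abs=1e-12
        )


class TestArchitecture:
    def test_default_shapes_and_fan_in(self, net_config, rng):
        state = build_architecture(net_config, rng)
        assert state.w1.shape == (4,)
        assert state.w2.shape == (4,)
        assert state.w3.shape == (4, 4)  # heteromodal fan-in of 4
        assert state.fan_in == (1, 1, 4)

    def test_degenerate_init_range(self, rng):
        cfg = NetworkConfig(weight_init_range=(0.5, 0.5))
        state = build_architecture(cfg, rng)
        for w in (state.w1, state.w2, state.w3):
            np.testing.assert_array_equal(w, np.full_like(w, 0.5))

    def test_seeded_determinism(self, net_config):
        a = build_architecture(net_config, np.random.default_rng(11))
        b = build_architecture(net_config, np.random.default_rng(11))
        np.testing.assert_array_equal(a.w3, b.w3)
        np.testing.assert_array_equal(a.w1, b.w1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(weight_init_range=(0.0, 1.2))
        with pytest.raises(ConfigurationError):
            NetworkConfig(n_levels=4)
        with pytest.raises(ConfigurationError):
            NetworkConfig(tracked_node_index=4)


class TestStepNetwork:
    def test_zero_eta_leaves_weights(self, net_config, rng):
        state = build_architecture(net_config, rng)
        cfg = net_config.replace(eta=0.0)
        new, deltas = step_network(state, np.full(4, 0.5), cfg)
        np.testing.assert_array_equal(new.w3, state.w3)
        assert all(np.all(d == 0.0) for d in deltas)

    def test_constant_input_geometric_level1(self, net_config, rng):
        state = build_architecture(net_config, rng)
        x = np.full(4, 0.55)
        gap0 = np.abs(state.w1 - x)
        for t in range(1, 6):
            state, _ = step_network(state, x, net_config)
            np.testing.assert_allclose(
                np.abs(state.w1 - x), gap0 * (1 - net_config.eta) ** t, atol=1e-12
            )

    def test_updates_use_preupdate_afferents(self, net_config, rng):
        state = build_architecture(net_config, rng)
        x = np.full(4, 0.5)
        y1, y2, _ = forward_pass(state, x)
        new, deltas = step_network(state, x, net_config)
        np.testing.assert_allclose(
            deltas[1], net_config.eta * np.abs(y1 - state.w2), atol=1e-15
        )
        np.testing.assert_allclose(
            deltas[2], net_config.eta * np.abs(y2[None, :] - state.w3), atol=1e-15
        )


class TestWorkMetrics:
    def test_direct_arithmetic(self):
        series = work_metrics([[0.1, 0.1]], "sum")
        assert series[0] == pytest.approx(0.2)
        assert work_metrics([[0.1, 0.1]], "sum_sq")[0] == pytest.approx(0.02)
        assert work_metrics([[0.1, 0.1]], "max")[0] == pytest.approx(0.1)

    def test_empty_iteration_is_zero(self):
        for metric in ("sum", "sum_sq", "max", "rate"):
            assert work_metrics([[]], metric)[0] == 0.0

    def test_no_cancellation_of_opposing_updates(self):
        """Opposing modifications of equal magnitude add; entropy cannot
        cancel across synapses."""
        assert work_metrics([[0.2, -0.2]], "sum")[0] == pytest.approx(0.4)

    def test_rate_equals_sum_on_unit_grid(self):
        deltas = [[0.1], [0.3, 0.1], [0.05]]
        np.testing.assert_allclose(
            work_metrics(deltas, "rate"), work_metrics(deltas, "sum")
        )

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigurationError):
            work_metrics([[0.1]], "median")


class TestEntropy:
    def test_uniform_four_outcomes(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(2.0)

    def test_degenerate_distribution(self):
        assert shannon_entropy([1.0, 0.0, 0.0, 0.0]) == 0.0

    def test_closed_form_biased_coin(self):
        assert shannon_entropy([0.25, 0.75]) == pytest.approx(0.81128, abs=1e-5)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            shannon_entropy([0.4, 0.4])

    def test_level_entropy_uniform_is_one(self):
        assert level_entropy([0.3, 0.3, 0.3, 0.3]) == pytest.approx(1.0)
        assert level_entropy([-0.3, 0.3]) == pytest.approx(1.0)  # magnitudes count

    def test_level_entropy_single_active_node_is_zero(self):
        assert level_entropy([0.0, 0.9, 0.0, 0.0]) == 0.0

    def test_level_entropy_via_shannon(self):
        assert level_entropy([0.2, 0.6]) == pytest.approx(0.81128, abs=1e-5)

    def test_level_entropy_all_zero_falls_back_to_uniform(self):
        assert level_entropy([0.0, 0.0, 0.0]) == pytest.approx(1.0)

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=8))
    @settings(max_examples=60, derandomize=True)
    def test_level_entropy_bounded(self, acts):
        h = level_entropy(acts)
        assert 0.0 <= h <= 1.0 + 1e-12


class TestLyapunovStep:
    def test_linear_gain_closed_form(self):
        """For a linear one-weight chain the single-pass exponent is ln of
        the end-to-end gain."""
        g1, g2 = 0.8, 0.6
        state = NetworkState(
            w1=np.full(4, g1),
            w2=np.full(4, g2),
            w3=np.eye(4) * 0.5,
            activation_kind="linear",
        )
        lam = lyapunov_step(state, np.full(4, 0.5), epsilon=1e-3)
        assert lam[0] == pytest.approx(math.log(g1), abs=1e-9)
        assert lam[1] == pytest.approx(math.log(g1 * g2), abs=1e-9)

    def test_saturated_tanh_is_strongly_negative(self, rng):
        state = NetworkState(
            w1=np.full(4, 50.0), w2=np.full(4, 50.0), w3=np.full((4, 4), 50.0)
        )
        lam = lyapunov_step(state, np.full(4, 1.0), epsilon=1e-3)
        assert np.all(lam < -5.0)

    def test_requires_positive_epsilon(self, net_config, rng):
        state = build_architecture(net_config, rng)
        with pytest.raises(ConfigurationError):
            lyapunov_step(state, np.full(4, 0.5), epsilon=0.0)


class TestRunTrial:
    def test_seeded_bit_reproducibility(self, net_config, stim_config):
        a = run_trial(net_config, stim_config, seed=123)
        b = run_trial(net_config, stim_config, seed=123)
        np.testing.assert_array_equal(a.delta_sum, b.delta_sum)
        np.testing.assert_array_equal(a.lyapunov, b.lyapunov)
        np.testing.assert_array_equal(a.entropy_norm, b.entropy_norm)

    def test_zero_eta_accumulates_no_work(self, stim_config):
        cfg = NetworkConfig(eta=0.0)
        trace = run_trial(cfg, stim_config, seed=5)
        np.testing.assert_array_equal(trace.work_cum, np.zeros_like(trace.work_cum))

    def test_cumulative_work_non_decreasing(self, net_config, stim_config):
        trace = run_trial(net_config, stim_config, seed=9)
        diffs = np.diff(trace.work_cum, axis=1)
        assert np.all(diffs >= -1e-15)

    def test_entropy_gen_is_per_synapse_delta_sum(self, net_config, stim_config):
        trace = run_trial(net_config, stim_config, seed=9)
        np.testing.assert_allclose(trace.entropy_gen[0], trace.delta_sum[0])
        np.testing.assert_allclose(trace.entropy_gen[2], trace.delta_sum[2] / 4.0)

    def test_entropy_norm_within_bounds(self, net_config, stim_config):
        trace = run_trial(net_config, stim_config, seed=9)
        assert np.all(trace.entropy_norm >= 0.0)
        assert np.all(trace.entropy_norm <= 1.0 + 1e-12)

    def test_trace_frame_schema(self, net_config, stim_config):
        df = run_trial(net_config, stim_config, seed=2).to_frame()
        assert list(df.columns) == [
            "trial_id", "level", "iteration", "delta_sum", "delta_sq",
            "delta_max", "work_cum", "entropy_norm", "lyapunov",
        ]
        assert len(df) == 3 * net_config.n_iterations


def test_work_increments_decline_with_learning(net_config, stim_config):
    """Entropy generation declines in expectation under constant-mean
    stimuli: the ensemble-mean increment late in learning is below the
    early-learning value at every level."""
    n = 200
    early, late = np.zeros(3), np.zeros(3)
    for k in range(n):
        tr = run_trial(net_config, stim_config, seed=3000 + k)
        early += tr.entropy_gen[:, 1]
        late += tr.entropy_gen[:, 14]
    assert np.all(late < early)
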