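"""Unit and property tests for the network core: inputs, sweeps, energies,
and the exact-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeodbm.core import (
    LayeredNetwork,
    NetworkState,
    SamplerConfig,
    _sweep,
    activation_prob,
    balanced_input,
    energy,
    exact_distribution,
    gibbs_sweep,
    layer_input,
    load_checkpoint,
    mean_field_sweep,
    run_trial,
    save_checkpoint,
    sigmoid,
    state_index,
    total_input,
)

from conftest import make_small_net


def random_state(net, seed=0, clamped=None):
    rng = np.random.default_rng(seed)
    states = [(rng.random(n) < 0.5).astype(float) for n in net.layer_sizes]
    return NetworkState(states, clamped or [False] * net.n_layers)


# ---------------------------------------------------------------------------
# total_input / activation_prob
# ---------------------------------------------------------------------------


def test_total_input_zero_parameters():
    net = make_small_net([3, 2], weight_scale=0.0, bias_scale=0.0)
    state = random_state(net)
    assert total_input(net, state, 1, 0) == 0.0


def test_total_input_single_connection():
    net = make_small_net([1, 1], weight_scale=0.0)
    net.weights[0][0, 0] = 2.0
    net.biases[1][0] = -1.0
    state = NetworkState([np.ones(1), np.zeros(1)], [False, False])
    assert total_input(net, state, 1, 0) == pytest.approx(1.0)


def test_total_input_matches_elementwise_oracle():
    net = make_small_net([5, 4, 3], seed=3)
    state = random_state(net, seed=4)
    for layer in range(3):
        for unit in range(net.layer_sizes[layer]):
            expected = net.biases[layer][unit]
            if layer > 0:
                for j in range(net.layer_sizes[layer - 1]):
                    expected += (
                        net.weights[layer - 1][j, unit] * state.layer_states[layer - 1][j]
                    )
            if layer < 2:
                for j in range(net.layer_sizes[layer + 1]):
                    expected += net.weights[layer][unit, j] * state.layer_states[layer + 1][j]
            assert total_input(net, state, layer, unit) == pytest.approx(expected)


def test_total_input_bad_indices():
    net = make_small_net([3, 2])
    state = random_state(net)
    with pytest.raises(IndexError):
        total_input(net, state, 5, 0)
    with pytest.raises(IndexError):
        total_input(net, state, 0, 10)


def test_activation_prob_midpoint_and_saturation():
    assert activation_prob(0.0) == 0.5
    assert activation_prob(50.0) == pytest.approx(1.0, abs=1e-9)
    assert activation_prob(-800.0) == 0.0  # saturates without overflow


@given(st.floats(-30, 30))
def test_activation_prob_symmetry(x):
    assert activation_prob(x) + activation_prob(-x) == pytest.approx(1.0)


@given(st.floats(-30, 30), st.floats(0.01, 10))
def test_activation_prob_monotone(x, dx):
    assert activation_prob(x + dx) > activation_prob(x)


# ---------------------------------------------------------------------------
# balanced input
# ---------------------------------------------------------------------------


def test_balanced_input_neutral_point_matches_total_input():
    net = make_small_net([4, 3, 2], seed=1)
    state = random_state(net, seed=2)
    balanced = balanced_input(net, state, 1, 0.5)
    plain = [total_input(net, state, 1, u) for u in range(3)]
    np.testing.assert_allclose(balanced, plain, rtol=0, atol=1e-12)


def test_balanced_input_endpoints():
    net = make_small_net([4, 3, 2], seed=1, bias_scale=0.0)
    state = random_state(net, seed=2)
    bu = state.layer_states[0] @ net.weights[0]
    td = state.layer_states[2] @ net.weights[1].T
    np.testing.assert_allclose(balanced_input(net, state, 1, 1.0), 2.0 * bu)
    np.testing.assert_allclose(balanced_input(net, state, 1, 0.0), 2.0 * td)


def test_balanced_input_rejects_end_layers():
    net = make_small_net([4, 3, 2])
    state = random_state(net)
    with pytest.raises(ValueError):
        balanced_input(net, state, 0, 0.5)
    with pytest.raises(ValueError):
        balanced_input(net, state, 2, 0.5)


# ---------------------------------------------------------------------------
# gibbs sweep
# ---------------------------------------------------------------------------


def test_gibbs_sweep_bernoulli_rate_matches_sigmoid_bias():
    # all layers clamped except one with zero weights: units are i.i.d.
    # Bernoulli(sigmoid(bias))
    net = make_small_net([2, 3], weight_scale=0.0, bias_scale=0.0)
    net.biases[1][:] = np.array([-1.0, 0.3, 1.2])
    state = NetworkState([np.zeros(2), np.zeros(3)], [True, False])
    rng = np.random.default_rng(0)
    cfg = SamplerConfig(cycles=1)
    n = 10_000
    total = np.zeros(3)
    for _ in range(n):
        out = gibbs_sweep(net, state, cfg, rng)
        total += out.layer_states[1]
    p = sigmoid(net.biases[1])
    se = np.sqrt(p * (1 - p) / n)
    assert np.all(np.abs(total / n - p) < 3 * se)


def test_gibbs_sweep_preserves_clamped_layers():
    net = make_small_net([4, 3, 2], seed=5)
    state = random_state(net, seed=6, clamped=[True, False, False])
    before = state.layer_states[0].copy()
    out = gibbs_sweep(net, state, SamplerConfig(), np.random.default_rng(1))
    assert np.array_equal(out.layer_states[0], before)


def test_gibbs_sweep_lambda_half_bit_identical_to_plain():
    net = make_small_net([4, 3, 2], seed=5)
    state = random_state(net, seed=6, clamped=[True, False, False])
    out_plain = gibbs_sweep(net, state, SamplerConfig(ach_lambda=None),
                            np.random.default_rng(7))
    out_half = gibbs_sweep(net, state, SamplerConfig(ach_lambda=0.5),
                           np.random.default_rng(7))
    for a, b in zip(out_plain.layer_states, out_half.layer_states):
        assert np.array_equal(a, b)


def test_sweep_all_clamped_is_an_error():
    net = make_small_net([2, 2])
    state = random_state(net, clamped=[True, True])
    with pytest.raises(ValueError):
        gibbs_sweep(net, state, SamplerConfig(), np.random.default_rng(0))


# ---------------------------------------------------------------------------
# mean-field sweep
# ---------------------------------------------------------------------------


def test_mean_field_zero_weights_fixed_point():
    net = make_small_net([2, 3], weight_scale=0.0, bias_scale=0.0)
    net.biases[1][:] = np.array([-2.0, 0.0, 1.0])
    state = NetworkState([np.zeros(2), np.zeros(3)], [True, False])
    out = mean_field_sweep(net, state, SamplerConfig(mode="mean_field"))
    np.testing.assert_allclose(out.layer_states[1], sigmoid(net.biases[1]))
    again = mean_field_sweep(net, out, SamplerConfig(mode="mean_field"))
    np.testing.assert_array_equal(again.layer_states[1], out.layer_states[1])


def test_mean_field_deterministic():
    net = make_small_net([4, 3, 2], seed=8)
    state = random_state(net, seed=9, clamped=[True, False, False])
    a = mean_field_sweep(net, state, SamplerConfig(mode="mean_field"))
    b = mean_field_sweep(net, state, SamplerConfig(mode="mean_field"))
    for x, y in zip(a.layer_states, b.layer_states):
        assert np.array_equal(x, y)


def test_mean_field_converges():
    net = make_small_net([4, 3, 2], seed=10)
    state = NetworkState(
        [np.ones(4) * 0.5, np.zeros(3), np.zeros(2)], [True, False, False]
    )
    cfg = SamplerConfig(mode="mean_field")
    deltas = []
    prev = state
    for _ in range(500):
        nxt = mean_field_sweep(net, prev, cfg)
        deltas.append(
            max(
                np.abs(a - b).max()
                for a, b in zip(nxt.layer_states[1:], prev.layer_states[1:])
            )
        )
        prev = nxt
    assert deltas[-1] < 1e-6
    burn = 50  # change magnitude must be non-increasing after burn-in
    assert all(b <= a + 1e-12 for a, b in zip(deltas[burn:-1], deltas[burn + 1 :]))


# ---------------------------------------------------------------------------
# energy and exact distribution
# ---------------------------------------------------------------------------


def test_energy_zero_state():
    net = make_small_net([3, 2], seed=11)
    state = NetworkState([np.zeros(3), np.zeros(2)], [False, False])
    assert energy(net, state) == 0.0


def test_energy_single_pair():
    net = make_small_net([1, 1], weight_scale=0.0, bias_scale=0.0)
    net.weights[0][0, 0] = 1.0
    state = NetworkState([np.ones(1), np.ones(1)], [False, False])
    assert energy(net, state) == pytest.approx(-1.0)


def test_energy_matches_double_loop_oracle():
    net = make_small_net([3, 3, 2], seed=12)
    state = random_state(net, seed=13)
    expected = 0.0
    for l, w in enumerate(net.weights):
        for i in range(w.shape[0]):
            for j in range(w.shape[1]):
                expected -= (
                    w[i, j] * state.layer_states[l][i] * state.layer_states[l + 1][j]
                )
    for l, b in enumerate(net.biases):
        for i, bi in enumerate(b):
            expected -= bi * state.layer_states[l][i]
    assert energy(net, state) == pytest.approx(expected)


def test_exact_distribution_uniform_when_parameters_zero():
    net = make_small_net([2, 2], weight_scale=0.0, bias_scale=0.0)
    p = exact_distribution(net)
    np.testing.assert_allclose(p, np.full(16, 1 / 16))


def test_exact_distribution_single_unit_bias():
    net = make_small_net([1, 1], weight_scale=0.0, bias_scale=0.0)
    b = 0.7
    net.biases[0][0] = b
    p = exact_distribution(net)
    # marginal of unit 0 (bit 0) being on
    on = p[1] + p[3]
    assert on == pytest.approx(sigmoid(b))


def test_exact_distribution_rejects_large_networks():
    net = make_small_net([12, 12], weight_scale=0.0)
    with pytest.raises(ValueError, match="enumeration"):
        exact_distribution(net)


def test_gibbs_chain_matches_exact_distribution_2x2():
    net = make_small_net([2, 2], seed=14, weight_scale=1.0, bias_scale=0.5)
    p = exact_distribution(net)
    states = [np.zeros(2), np.zeros(2)]
    counts = np.zeros(16)
    rng = np.random.default_rng(15)
    for _ in range(200_000):
        _sweep(net, states, [False, False], None, rng, False)
        counts[state_index(net, states)] += 1
    tv = 0.5 * np.abs(counts / counts.sum() - p).sum()
    assert tv < 0.05


def test_detailed_balance_single_flip_frequency_ratio():
    net = make_small_net([2, 2], seed=16, weight_scale=0.8, bias_scale=0.4)
    states = [np.zeros(2), np.zeros(2)]
    counts = np.zeros(16)
    rng = np.random.default_rng(17)
    for _ in range(300_000):
        _sweep(net, states, [False, False], None, rng, False)
        counts[state_index(net, states)] += 1
    # compare two joint states differing in one unit (bit 0)
    s0 = [np.array([0.0, 1.0]), np.array([1.0, 0.0])]
    s1 = [np.array([1.0, 1.0]), np.array([1.0, 0.0])]
    i0, i1 = state_index(net, s0), state_index(net, s1)
    ratio = counts[i1] / counts[i0]
    expected = np.exp(energy(net, s0) - energy(net, s1))
    assert ratio == pytest.approx(expected, rel=0.1)


# ---------------------------------------------------------------------------
# invariants and containers
# ---------------------------------------------------------------------------


def test_masked_weights_stay_zero_through_network_validation():
    rng = np.random.default_rng(0)
    mask = (rng.random((4, 3)) < 0.5).astype(float)
    w = rng.normal(size=(4, 3)) * mask
    net = LayeredNetwork([4, 3], [w], [np.zeros(4), np.zeros(3)], [mask])
    assert np.all(net.weights[0][mask == 0] == 0)
    bad = w.copy()
    bad[mask == 0] = 1.0
    with pytest.raises(ValueError, match="mask"):
        LayeredNetwork([4, 3], [bad], [np.zeros(4), np.zeros(3)], [mask])


def test_run_trial_clamping_conserved_over_many_sweeps():
    net = make_small_net([4, 3, 2], seed=18)
    visible = np.array([1.0, 0.0, 0.5, 0.25])  # grey-scale clamp
    state = NetworkState.from_visible(net, visible)
    for mode in ("stochastic", "mean_field"):
        out, _ = run_trial(net, state, SamplerConfig(cycles=20, mode=mode),
                           np.random.default_rng(19))
        assert np.array_equal(out.layer_states[0], visible)


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(cycles=0)
    with pytest.raises(ValueError):
        SamplerConfig(ach_lambda=1.5)
    with pytest.raises(ValueError):
        SamplerConfig(mode="annealed")


def test_checkpoint_roundtrip_and_version_rejection(tmp_path):
    net = make_small_net([4, 3, 2], seed=20)
    net.visible_shape = (2, 2)
    path = tmp_path / "model.npz"
    save_checkpoint(net, str(path))
    loaded = load_checkpoint(str(path))
    assert loaded.layer_sizes == net.layer_sizes
    assert loaded.visible_shape == (2, 2)
    for a, b in zip(loaded.weights, net.weights):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(loaded.biases, net.biases):
        np.testing.assert_array_equal(a, b)

    # tamper with the version
    import json

    data = dict(np.load(path, allow_pickle=False))
    meta = json.loads(str(data["metadata_json"]))
    meta["format_version"] = 999
    data["metadata_json"] = np.array(json.dumps(meta))
    np.savez(path, **data)
    with pytest.raises(ValueError, match="version"):
        load_checkpoint(str(path))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_layer_input_lambda_half_exact_identity(seed):
    net = make_small_net([3, 4, 3], seed=21)
    rng = np.random.default_rng(seed)
    states = [(rng.random(n) < 0.5).astype(float) for n in net.layer_sizes]
    plain = layer_input(net, states, 1, None)
    half = layer_input(net, states, 1, 0.5)
    assert np.array_equal(plain, half)
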