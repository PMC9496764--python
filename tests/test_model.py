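import math

import numpy as np
import pytest

from gcfn.model import (
    FusionNet,
    GCFNConfig,
    build_cwt_cnn,
    build_eeg_gru,
    build_gcfn,
    gru_cell_step,
    gru_param_count,
)
from gcfn.trainer_eval import cross_entropy

TINY = GCFNConfig(
    cnn_filters=2, cnn_kernel=(8, 1), gru1_units=3, gru2_units=4,
    fc1_units=5, dropout_p=0.0, eeg_input=(7, 3), image_input=(8, 6, 1),
)


def naive_gru_sequence(xs, h0, params):
    """Scalar-loop recurrence of the gated update; the independent oracle."""
    u = len(h0)
    Wx, Wh, bx, bh = params["Wx"], params["Wh"], params["bx"], params["bh"]
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = list(h0)
    for x in xs:
        xg = [sum(x[i] * Wx[i][j] for i in range(len(x))) + bx[j] for j in range(3 * u)]
        hg = [sum(h[i] * Wh[i][j] for i in range(u)) + bh[j] for j in range(3 * u)]
        r = [sig(xg[j] + hg[j]) for j in range(u)]
        z = [sig(xg[u + j] + hg[u + j]) for j in range(u)]
        g = [math.tanh(xg[2 * u + j] + r[j] * hg[2 * u + j]) for j in range(u)]
        h = [(1.0 - z[j]) * h[j] + z[j] * g[j] for j in range(u)]
    return np.array(h)


def _gru_params(rng, n_in, units):
    return {
        "Wx": rng.standard_normal((n_in, 3 * units)),
        "Wh": rng.standard_normal((units, 3 * units)),
        "bx": rng.standard_normal(3 * units),
        "bh": rng.standard_normal(3 * units),
    }


class TestGruCell:
    def test_zero_fixed_point(self):
        params = {k: np.zeros(s) for k, s in
                  [("Wx", (2, 6)), ("Wh", (2, 6)), ("bx", 6), ("bh", 6)]}
        h = gru_cell_step(np.ones(2), np.zeros(2), params)
        np.testing.assert_array_equal(h, np.zeros((1, 2)))

    def test_saturated_update_gate_tracks_candidate(self, rng):
        """With the update gate forced open, the state equals the candidate."""
        params = _gru_params(rng, 2, 2)
        params["bx"][2:4] = 50.0  # update-gate bias -> z ~= 1
        x, h_prev = rng.standard_normal(2), rng.standard_normal(2)
        u = 2
        xg = x @ params["Wx"] + params["bx"]
        hg = h_prev @ params["Wh"] + params["bh"]
        r = 1.0 / (1.0 + np.exp(-(xg[:u] + hg[:u])))
        g = np.tanh(xg[2 * u:] + r * hg[2 * u:])
        h = gru_cell_step(x, h_prev, params)
        np.testing.assert_allclose(h[0], g, atol=1e-10)

    def test_scalar_oracle_single_unit(self, rng):
        params = _gru_params(rng, 1, 1)
        xs = rng.standard_normal((3, 1))
        h = np.zeros(1)
        for x in xs:
            h = gru_cell_step(x, h, params)[0]
        np.testing.assert_allclose(h, naive_gru_sequence(xs, np.zeros(1), params),
                                   rtol=1e-12)

    def test_layer_equals_composed_cell_steps(self, rng):
        net = build_eeg_gru(TINY, seed=3)
        xs = rng.standard_normal((2, 7, 3))
        seq1 = net.gru1.forward(xs)
        h = np.zeros((2, 3))
        for t in range(7):
            h = gru_cell_step(xs[:, t], h, net.gru1.params)
            np.testing.assert_allclose(seq1[:, t], h, atol=1e-5)
        h2_layer = net.gru2.forward(seq1)
        h2 = np.zeros((2, 4))
        for t in range(7):
            h2 = gru_cell_step(seq1[:, t], h2, net.gru2.params)
        np.testing.assert_allclose(h2_layer, h2, atol=1e-5)
        # deeper cross-check against the naive scalar recurrence
        np.testing.assert_allclose(
            h2[0], naive_gru_sequence(seq1[0], np.zeros(4), net.gru2.params), rtol=1e-9
        )

    def test_dimension_mismatch_rejected(self, rng):
        params = _gru_params(rng, 2, 3)
        with pytest.raises(ValueError, match="inconsistent"):
            gru_cell_step(np.zeros(5), np.zeros(3), params)


class TestArchitecture:
    def test_published_parameter_counts(self):
        net = build_gcfn()
        counts = {r["layer"]: r["params"] for r in net.summary()}
        assert counts["Conv2D"] == 14_400
        assert counts["GRU1"] == 3_675
        assert counts["GRU2"] == 11_550
        assert counts["FC1"] == 260_480
        assert counts["FC2"] == 516

    def test_two_bias_convention_is_forced(self):
        # the published counts match only the two-bias formulation
        assert gru_param_count(22, 25) == 3_675
        assert gru_param_count(25, 50) == 11_550
        one_bias = lambda i, u: 3 * (u * (i + u) + u)
        assert one_bias(22, 25) != 3_675
        assert one_bias(25, 50) != 11_550

    def test_derived_geometry(self):
        cfg = GCFNConfig()
        assert cfg.conv_out_width == 93
        assert cfg.pool_out_width == 31
        assert cfg.flatten_len == 1984
        assert cfg.fused_len == 2034

    def test_ablation_classifier_sizes(self):
        assert build_eeg_gru().fc1.n_params == 50 * 128 + 128
        assert build_cwt_cnn().fc1.n_params == 1984 * 128 + 128  # 254,080

    def test_config_validation(self):
        with pytest.raises(ValueError, match="kernel height"):
            GCFNConfig(cnn_kernel=(100, 1))
        with pytest.raises(ValueError, match="dropout"):
            GCFNConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            GCFNConfig(gru1_units=0)


class TestForward:
    def test_probability_rows(self, rng):
        net = build_gcfn(TINY, seed=0)
        p = net.forward(rng.standard_normal((5, 7, 3)), rng.random((5, 8, 6)))
        assert p.shape == (5, 4)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_parameters_give_uniform_output(self, rng):
        net = build_gcfn(TINY, seed=0)
        for layer in net.layers:
            for k in layer.params:
                layer.params[k][...] = 0.0
        p = net.forward(rng.standard_normal((3, 7, 3)), rng.random((3, 8, 6)))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        net = build_gcfn(TINY, seed=0)
        with pytest.raises(ValueError, match="image batch"):
            net.forward(rng.standard_normal((2, 7, 3)), rng.random((2, 9, 6)))
        with pytest.raises(ValueError, match="EEG batch"):
            net.forward(rng.standard_normal((2, 6, 3)), rng.random((2, 8, 6)))
        with pytest.raises(ValueError, match="batch sizes"):
            net.forward(rng.standard_normal((2, 7, 3)), rng.random((3, 8, 6)))

    def test_branch_input_required(self, rng):
        with pytest.raises(ValueError, match="image"):
            build_cwt_cnn(TINY).forward(None, None)
        with pytest.raises(ValueError, match="EEG"):
            build_eeg_gru(TINY).forward(None, None)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Central-difference check across every layer's parameters."""
        net = build_gcfn(TINY, seed=0)
        eeg = rng.standard_normal((4, 7, 3))
        img = rng.random((4, 8, 6))
        y = np.zeros((4, 4))
        y[np.arange(4), [0, 1, 2, 3]] = 1.0

        probs = net.forward(eeg, img)
        net.zero_grads()
        net.backward((probs - y) / 4)

        def loss():
            return cross_entropy(net.forward(eeg, img), y)

        for layer in net.layers:
            for k, P in layer.params.items():
                G = layer.grads[k]
                for _ in range(3):
                    ij = tuple(rng.integers(s) for s in P.shape)
                    eps, old = 1e-6, P[ij]
                    P[ij] = old + eps
                    lp = loss()
                    P[ij] = old - eps
                    lm = loss()
                    P[ij] = old
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - G[ij]) <= 1e-5 * max(1.0, abs(num))
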