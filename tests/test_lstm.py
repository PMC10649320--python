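import copy

import numpy as np
import pytest

from pirlstm import batch_encode
from pirlstm.nn import (
    NetworkConfig,
    LstmLayerParams,
    init_weights,
    load_checkpoint,
    lstm_cell_step,
    lstm_layer_forward,
    network_forward,
    network_forward_backward,
    predict_classes,
    reference_cell_step,
    reference_layer_forward,
    save_checkpoint,
    softmax,
)
from pirlstm.nn.network import _forward
from pirlstm.training import loss_cross_entropy


def _random_params(H, D, rng, forget_bias=0.0):
    W = rng.normal(scale=0.5, size=(4 * H, H + D))
    b = rng.normal(scale=0.3, size=4 * H)
    b[H:2 * H] += forget_bias
    return LstmLayerParams(W=W, b=b)


def _as_gate_lists(params):
    """Per-gate (W, b) as plain Python lists for the reference cell."""
    out = []
    for gate in (params.input_gate, params.forget_gate,
                 params.output_gate, params.candidate):
        W, b = gate
        out += [W.tolist(), b.tolist()]
    Wi, bi, Wf, bf, Wo, bo, Wc, bc = out
    return Wi, bi, Wf, bf, Wo, bo, Wc, bc


class TestCellStep:
    def test_all_zero_weights_zero_state(self, rng):
        H, D = 4, 3
        params = LstmLayerParams(W=np.zeros((4 * H, H + D)), b=np.zeros(4 * H))
        h, c = lstm_cell_step(params, (np.zeros(H), np.zeros(H)), rng.normal(size=D))
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_zero_weights_nonzero_cell_state(self, rng):
        # all gates sit at sigmoid(0)=0.5 and the candidate at tanh(0)=0
        H, D = 3, 2
        params = LstmLayerParams(W=np.zeros((4 * H, H + D)), b=np.zeros(4 * H))
        c0 = np.array([1.0, -2.0, 0.5])
        h, c = lstm_cell_step(params, (np.zeros(H), c0), rng.normal(size=D))
        np.testing.assert_allclose(c, 0.5 * c0)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c0))

    def test_scalar_case_matches_reference(self, rng):
        params = _random_params(1, 1, rng)
        h_prev, c_prev = rng.normal(size=1), rng.normal(size=1)
        x = rng.normal(size=1)
        h, c = lstm_cell_step(params, (h_prev, c_prev), x)
        rh, rc = reference_cell_step(
            *_as_gate_lists(params), h_prev.tolist(), c_prev.tolist(), x.tolist())
        np.testing.assert_allclose(h, rh, atol=1e-9)
        np.testing.assert_allclose(c, rc, atol=1e-9)


class TestLayerForward:
    @pytest.mark.parametrize("H", [1, 2, 4])
    def test_oracle_equivalence_random_draws(self, H, rng):
        """Vectorized layer pass equals the scalar from-equations oracle."""
        D = 4
        for _ in range(34):  # ~100 draws across the three H values
            params = _random_params(H, D, rng)
            L = int(rng.integers(1, 13))
            inputs = rng.normal(size=(L, D))
            (h, c), trace = lstm_layer_forward(params, inputs)
            rh, rc, rtrace = reference_layer_forward(
                *_as_gate_lists(params), inputs.tolist())
            np.testing.assert_allclose(h, rh, atol=1e-6)
            np.testing.assert_allclose(c, rc, atol=1e-6)
            np.testing.assert_allclose(trace, rtrace, atol=1e-6)

    def test_chained_8_steps_matches_reference(self, rng):
        params = _random_params(2, 3, rng)
        inputs = rng.normal(size=(8, 3))
        (h, c), _ = lstm_layer_forward(params, inputs)
        rh, rc, _ = reference_layer_forward(*_as_gate_lists(params), inputs.tolist())
        np.testing.assert_allclose(h, rh, atol=1e-9)
        np.testing.assert_allclose(c, rc, atol=1e-9)

    def test_padding_rows_never_consumed(self, rng):
        params = _random_params(3, 4, rng)
        inputs = rng.normal(size=(6, 4))
        padded = np.vstack([inputs, np.zeros((5, 4))])
        (h1, c1), _ = lstm_layer_forward(params, inputs, length=6)
        (h2, c2), _ = lstm_layer_forward(params, padded, length=6)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(c1, c2)

    def test_hidden_state_bounded(self, rng):
        params = _random_params(4, 4, rng)
        params.W *= 10  # push activations toward saturation
        _, trace = lstm_layer_forward(params, rng.normal(size=(12, 4)))
        assert np.all(np.abs(trace) < 1.0)

    def test_forget_and_input_gates_closed_kills_cell_state(self, rng):
        H, D = 3, 2
        params = _random_params(H, D, rng)
        params.b[0:H] = -50.0        # input gate -> 0
        params.b[H:2 * H] = -50.0    # forget gate -> 0
        params.W[0:2 * H] = 0.0
        (h, c), _ = lstm_layer_forward(params, rng.normal(size=(10, D)))
        np.testing.assert_allclose(c, 0.0, atol=1e-20)

    def test_zero_length_rejected(self, rng):
        params = _random_params(2, 4, rng)
        with pytest.raises(ValueError):
            lstm_layer_forward(params, rng.normal(size=(3, 4)), length=0)


class TestNetworkForward:
    def _fitted(self, rng, B=4, hidden=6, n_layers=2):
        cfg = NetworkConfig(n_layers=n_layers, hidden_size=hidden, dropout_rate=0.0)
        w = init_weights(cfg, rng)
        seqs = ["".join(rng.choice(list("AUCG"), size=int(n)))
                for n in rng.integers(8, 20, size=B)]
        eb = batch_encode(seqs, rng.integers(0, 2, size=B))
        # one train-mode pass to populate batch-norm running moments
        network_forward_backward(cfg, w, eb, eb.labels, rng)
        return cfg, w, eb, seqs

    def test_output_shape(self, rng):
        cfg, w, eb, _ = self._fitted(rng, B=3)
        assert network_forward(cfg, w, eb, "eval").shape == (3, 2)

    def test_eval_mode_deterministic(self, rng):
        cfg, w, eb, _ = self._fitted(rng)
        a = network_forward(cfg, w, eb, "eval")
        b = network_forward(cfg, w, eb, "eval")
        np.testing.assert_array_equal(a, b)

    def test_padding_invariance_eval_logits(self, rng):
        cfg, w, eb, seqs = self._fitted(rng)
        base = network_forward(cfg, w, eb, "eval")
        padded = np.concatenate(
            [eb.tensor, np.zeros((len(seqs), 10, 4))], axis=1)
        eb2 = copy.deepcopy(eb)
        eb2.tensor = padded
        np.testing.assert_allclose(network_forward(cfg, w, eb2, "eval"),
                                   base, atol=1e-6)

    def test_eval_before_training_is_an_error(self, rng):
        cfg = NetworkConfig(n_layers=1, hidden_size=4)
        w = init_weights(cfg, rng)
        eb = batch_encode(["AUCG"])
        with pytest.raises(RuntimeError, match="running moments"):
            network_forward(cfg, w, eb, "eval")


class TestBackwardPass:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic BPTT gradients agree with central differences."""
        cfg = NetworkConfig(n_layers=3, hidden_size=5, dropout_rate=0.0)
        w = init_weights(cfg, rng)
        eb = batch_encode(["AUCGAUCGAU", "AUCG", "GGGCCAUU", "NNAUCG"],
                          [1, 0, 1, 0])

        def loss_at(weights):
            w2 = copy.deepcopy(weights)
            logits, _ = _forward(cfg, w2, eb, "train", None, False)
            return loss_cross_entropy(logits, eb.labels)

        _, _, grads = network_forward_backward(
            cfg, copy.deepcopy(w), eb, eb.labels, None)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for name, arr in w.trainable():
            flat = check_rng.choice(arr.size, size=min(6, arr.size), replace=False)
            for k in flat:
                ix = np.unravel_index(k, arr.shape)
                wp = copy.deepcopy(w)
                dict(wp.trainable())[name][ix] += eps
                wm = copy.deepcopy(w)
                dict(wm.trainable())[name][ix] -= eps
                num = (loss_at(wp) - loss_at(wm)) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, abs=1e-5), name


class TestPredictClasses:
    def test_confident_pirna(self):
        classes, scores = predict_classes(np.array([[0.0, 10.0]]))
        assert classes.tolist() == [1]
        assert scores[0] == pytest.approx(1.0, abs=1e-4)

    def test_tie_goes_to_non_pirna(self):
        classes, scores = predict_classes(np.array([[3.0, 3.0]]))
        assert classes.tolist() == [0]
        assert scores[0] == pytest.approx(0.5)

    def test_softmax_rows_normalized(self, rng):
        p = softmax(rng.normal(size=(20, 2)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            predict_classes(np.array([[np.nan, 0.0]]))


class TestCheckpoint:
    def test_round_trip_reproduces_eval_function(self, tmp_path, rng):
        cfg = NetworkConfig(n_layers=2, hidden_size=4, dropout_rate=0.1)
        w = init_weights(cfg, rng)
        eb = batch_encode(["AUCGAUCG", "GCAU"], [1, 0])
        network_forward_backward(cfg, w, eb, eb.labels, rng)
        path = tmp_path / "m.ckpt"
        save_checkpoint(path, cfg, w, extra={"seed": 1})
        cfg2, w2, extra = load_checkpoint(path)
        assert extra == {"seed": 1}
        np.testing.assert_array_equal(network_forward(cfg, w, eb, "eval"),
                                      network_forward(cfg2, w2, eb, "eval"))
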