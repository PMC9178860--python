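"""Reference oracles vs the vectorized layers, gradients, and training."""

import numpy as np
import pytest

import methylsite as ms
from methylsite.network import (
    DCBConfig,
    DCBNetwork,
    LSTMCellParams,
    dilated_conv_batch,
)


def rand_lstm_params(rng, d, H):
    n = lambda *s: rng.normal(scale=0.4, size=s)
    return LSTMCellParams(
        Wf=n(H, d), Wi=n(H, d), Wc=n(H, d), Wo=n(H, d),
        Uf=n(H, H), Ui=n(H, H), Uc=n(H, H), Uo=n(H, H),
        bf=n(H), bi=n(H), bc=n(H), bo=n(H),
    )


class TestDilatedConvRef:
    def test_hand_example(self):
        spec = ms.DilatedConvSpec(weights=np.array([1.0, 1.0]), rate=2)
        out = ms.dilated_conv1d_ref(np.array([1.0, 2, 3, 4, 5]), spec)
        assert out.tolist() == [8.0]  # x_3 + x_5

    def test_r1_equals_brute_force_sliding_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(5, 30))
            N = int(rng.integers(1, 4))
            x = rng.normal(size=L)
            w = rng.normal(size=N)
            b = float(rng.normal())
            spec = ms.DilatedConvSpec(weights=w, bias=b, rate=1)
            out = ms.dilated_conv1d_ref(x, spec)
            brute = np.array(
                [x[j + 1 : j + 1 + N] @ w + b for j in range(L - N)])
            np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_zero_weights_give_activated_bias(self):
        spec = ms.DilatedConvSpec(weights=np.zeros(3), bias=-1.5, rate=2,
                                  activation=ms.relu)
        out = ms.dilated_conv1d_ref(np.ones(10), spec)
        assert np.all(out == 0.0)  # relu(-1.5)

    def test_too_short_input(self):
        spec = ms.DilatedConvSpec(weights=np.ones(3), rate=2)
        with pytest.raises(ValueError):
            ms.dilated_conv1d_ref(np.ones(6), spec)

    def test_onesided_is_shifted_standard(self):
        """The literal one-sided form equals the framework convention
        shifted by the dilation rate."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = int(rng.integers(1, 4))
            N = int(rng.integers(1, 4))
            L = int(rng.integers(r * N + 2, r * N + 20))
            spec = ms.DilatedConvSpec(
                weights=rng.normal(size=N), bias=float(rng.normal()), rate=r)
            x = rng.normal(size=L)
            ref = ms.dilated_conv1d_ref(x, spec)
            std = ms.dilated_conv1d_standard(x, spec)
            np.testing.assert_allclose(ref, std[r:], atol=1e-12)

    def test_batched_layer_matches_per_channel_reference(self):
        """The vectorized multi-channel layer equals channelwise sums of the
        single-channel reference on random instances."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            B = int(rng.integers(1, 3))
            d = int(rng.integers(1, 4))
            F = int(rng.integers(1, 4))
            N = int(rng.integers(1, 4))
            r = int(rng.integers(1, 4))
            L = int(rng.integers(r * (N - 1) + 1, r * N + 12))
            X = rng.normal(size=(B, L, d))
            W = rng.normal(size=(N, d, F))
            b = rng.normal(size=F)
            out = dilated_conv_batch(X, W, b, r)
            for bi in range(B):
                for f in range(F):
                    acc = np.full(L - r * (N - 1), b[f])
                    for c in range(d):
                        spec = ms.DilatedConvSpec(
                            weights=W[:, c, f], bias=0.0, rate=r)
                        acc += ms.dilated_conv1d_standard(X[bi, :, c], spec)
                    np.testing.assert_allclose(out[bi, :, f], acc, atol=1e-5)


class TestLSTMRef:
    def test_all_zero_closed_form(self):
        p = LSTMCellParams.zeros(3, 2)
        h, C, gates = ms.lstm_step_ref(np.zeros(3), np.zeros(2), np.zeros(2), p)
        assert np.all(gates["f"] == 0.5) and np.all(gates["i"] == 0.5)
        assert np.all(gates["C_tilde"] == 0.0)
        assert np.all(C == 0.0) and np.all(h == 0.0)

    def test_carry_closed_form(self):
        p = LSTMCellParams.zeros(3, 2)
        h, C, _ = ms.lstm_step_ref(np.zeros(3), np.zeros(2), np.full(2, 2.0), p)
        np.testing.assert_allclose(C, 1.0)  # f=0.5 halves C_prev=2
        np.testing.assert_allclose(h, 0.5 * np.tanh(1.0), atol=1e-12)

    def test_gates_strictly_in_unit_interval(self):
        rng = np.random.default_rng(3)
        p = rand_lstm_params(rng, 4, 3)
        for _ in range(10):
            _, _, gates = ms.lstm_step_ref(
                rng.normal(size=4), rng.normal(size=3), rng.normal(size=3), p)
            for key in ("f", "i", "o"):
                assert np.all((gates[key] > 0) & (gates[key] < 1))

    def test_shape_mismatch(self):
        p = LSTMCellParams.zeros(3, 2)
        with pytest.raises(ValueError):
            ms.lstm_step_ref(np.zeros(4), np.zeros(2), np.zeros(2), p)


class TestBiLSTMRef:
    def test_single_step_width(self):
        rng = np.random.default_rng(4)
        fwd, bwd = rand_lstm_params(rng, 3, 2), rand_lstm_params(rng, 3, 2)
        out = ms.bilstm_ref(rng.normal(size=(1, 3)), fwd, bwd)
        assert out.shape == (1, 4)

    def test_palindromic_symmetry(self):
        rng = np.random.default_rng(5)
        p = rand_lstm_params(rng, 3, 2)
        half = rng.normal(size=(4, 3))
        X = np.vstack([half, half[::-1]])
        out = ms.bilstm_ref(X, p, p)
        H = p.H
        np.testing.assert_allclose(out[:, :H], out[::-1, H:], atol=1e-12)

    def test_matches_vectorized_layer(self):
        """Reference step iteration vs the trainable network's batched LSTM
        with identical packed parameters on 100 random instances."""
        rng = np.random.default_rng(6)
        cfg = DCBConfig(n_filters=2, bilstm_units=3, dense_sizes=(4,),
                        seed=0)
        net = DCBNetwork(cfg, (12, 5), "onehot")
        C = 2 * 3  # filters * n_blocks
        fwd = LSTMCellParams.from_packed(
            net.params["fw_Wx"], net.params["fw_Wh"], net.params["fw_b"])
        bwd = LSTMCellParams.from_packed(
            net.params["bw_Wx"], net.params["bw_Wh"], net.params["bw_b"])
        for _ in range(100):
            X = rng.normal(size=(1, net.T, C))
            ref = ms.bilstm_ref(X[0], fwd, bwd)
            Hf, _ = net._lstm_forward(X, "fw")
            Hb, _ = net._lstm_forward(X[:, ::-1], "bw")
            vec = np.concatenate([Hf[0], Hb[0, ::-1]], axis=1)
            np.testing.assert_allclose(ref, vec, atol=1e-5)

    def test_packed_round_trip(self):
        rng = np.random.default_rng(7)
        p = rand_lstm_params(rng, 4, 3)
        q = LSTMCellParams.from_packed(*p.to_packed())
        np.testing.assert_array_equal(p.Wc, q.Wc)
        np.testing.assert_array_equal(p.Uo, q.Uo)
        np.testing.assert_array_equal(p.bf, q.bf)


class TestBuildDCB:
    def test_default_config_values(self):
        cfg = DCBConfig()
        assert (cfg.n_filters, cfg.kernel_size) == (64, 3)
        assert cfg.dilation_rates == (1, 2, 3)
        assert cfg.pool_size == 2
        assert cfg.conv_dropout == 0.2
        assert (cfg.bilstm_units, cfg.bilstm_dropout) == (64, 0.2)
        assert cfg.dense_sizes == (256, 128, 64)
        assert cfg.dense_dropout == 0.5

    def test_first_conv_block_parameter_count(self):
        net = ms.build_dcb(DCBConfig(), (99, 300), "rglove")
        n = net.params["convW1"].size + net.params["convb1"].size
        assert n == (3 * 300 + 1) * 64  # 57,664

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(8)
        cfg = DCBConfig(n_filters=4, bilstm_units=3, dense_sizes=(8,))
        net = ms.build_dcb(cfg, (15, 5), "onehot")
        p = net.predict_proba(rng.normal(size=(6, 15, 5)))
        assert np.all((p > 0) & (p < 1))

    def test_too_short_input_reports_minimum(self):
        cfg = DCBConfig()
        with pytest.raises(ValueError, match=str(cfg.min_input_length())):
            ms.build_dcb(cfg, (5, 5), "onehot")

    def test_sigmoid_at_zero_logit(self):
        assert ms.sigmoid(np.zeros(1))[0] == 0.5


class TestGradientsEndToEnd:
    @pytest.mark.parametrize("encoder", ["onehot", "embedding"])
    def test_backprop_matches_finite_differences(self, encoder):
        rng = np.random.default_rng(9)
        cfg = DCBConfig(n_filters=3, kernel_size=3, bilstm_units=2,
                        dense_sizes=(6, 4), conv_dropout=0.0,
                        bilstm_dropout=0.0, dense_dropout=0.0, seed=5)
        if encoder == "onehot":
            net = DCBNetwork(cfg, (14, 5), "onehot")
            Xb = rng.normal(size=(4, 14, 5))
        else:
            net = DCBNetwork(cfg, (14, 6), "embedding", vocab_size=10)
            Xb = rng.integers(1, 11, size=(4, 14))
        yb = np.array([0.0, 1, 1, 0])
        _, cache = net.forward(Xb, training=True,
                               rng=np.random.default_rng(0))
        grads = net.backward(cache, yb)
        eps = 1e-6
        for name, P in net.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in P.shape)
                if name == "embed" and idx[0] == 0:
                    continue  # frozen pad row
                orig = P[idx]
                P[idx] = orig + eps
                up = net.loss(net.forward(Xb)[0], yb)
                P[idx] = orig - eps
                down = net.loss(net.forward(Xb)[0], yb)
                P[idx] = orig
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(grads[name][idx], rel=1e-4,
                                           abs=1e-8), name

    def test_dropout_gradients_match_with_fixed_masks(self):
        rng = np.random.default_rng(10)
        cfg = DCBConfig(n_filters=3, bilstm_units=2, dense_sizes=(6,),
                        seed=5)  # default dropout rates active
        net = DCBNetwork(cfg, (14, 5), "onehot")
        Xb = rng.normal(size=(3, 14, 5))
        yb = np.array([0.0, 1, 0])

        def loss_with_masks():
            p, c = net.forward(Xb, training=True,
                               rng=np.random.default_rng(99))
            return net.loss(p, yb), c

        _, cache = loss_with_masks()
        grads = net.backward(cache, yb)
        eps = 1e-6
        for name in ("convW1", "fw_Wx", "denseW0", "outW"):
            P = net.params[name]
            idx = tuple(rng.integers(0, s) for s in P.shape)
            orig = P[idx]
            P[idx] = orig + eps
            up, _ = loss_with_masks()
            P[idx] = orig - eps
            down, _ = loss_with_masks()
            P[idx] = orig
            fd = (up - down) / (2 * eps)
            assert fd == pytest.approx(grads[name][idx], rel=1e-4, abs=1e-8)


@pytest.fixture(scope="module")
def encoded_small(small_dataset):
    windows, _ = small_dataset
    y = np.array([w.label for w in windows], float)
    X = ms.encode_windows([w.window for w in windows], "onehot")
    return X, y


class TestTraining:
    def scaled_cfg(self, **kw):
        base = dict(n_filters=4, bilstm_units=4, dense_sizes=(16,),
                    epochs=3, seed=1)
        base.update(kw)
        return DCBConfig(**base)

    def test_deterministic_history(self, encoded_small):
        X, y = encoded_small
        runs = []
        for _ in range(2):
            net = ms.build_dcb(self.scaled_cfg(), (21, 5), "onehot")
            pred = ms.train_predictor(net, X, y)
            runs.append(pred.history["loss"])
        assert runs[0] == runs[1]

    def test_loss_decreases_on_separable_data(self, encoded_small):
        X, y = encoded_small
        cfg = self.scaled_cfg(epochs=5, conv_dropout=0.0, bilstm_dropout=0.0,
                              dense_dropout=0.0)
        net = ms.build_dcb(cfg, (21, 5), "onehot")
        pred = ms.train_predictor(net, X, y)
        losses = pred.history["loss"]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_single_class_rejected(self, encoded_small):
        X, _ = encoded_small
        net = ms.build_dcb(self.scaled_cfg(), (21, 5), "onehot")
        with pytest.raises(ValueError):
            ms.train_predictor(net, X, np.ones(len(X)))

    def test_batched_and_single_prediction_agree(self, encoded_small):
        X, y = encoded_small
        net = ms.build_dcb(self.scaled_cfg(), (21, 5), "onehot")
        pred = ms.train_predictor(net, X, y)
        batched = pred.predict_proba(X[:10])
        singles = np.concatenate(
            [pred.predict_proba(X[i : i + 1]) for i in range(10)])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_save_load_round_trip(self, encoded_small, tmp_path):
        X, y = encoded_small
        net = ms.build_dcb(self.scaled_cfg(), (21, 5), "onehot")
        pred = ms.train_predictor(net, X, y)
        pred.save(tmp_path / "model")
        loaded = ms.TrainedPredictor.load(tmp_path / "model")
        np.testing.assert_array_equal(
            pred.predict_proba(X[:8]), loaded.predict_proba(X[:8]))

    def test_encoder_input_mismatch_rejected(self, encoded_small):
        X, y = encoded_small
        net = ms.build_dcb(self.scaled_cfg(), (21, 5), "onehot")
        with pytest.raises(ValueError):
            net.predict_proba(np.zeros((2, 21), dtype=np.int64))
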