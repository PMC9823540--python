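"""Bi-CLSTM head: gate equations, fusion, residual blocks, focal loss."""

import numpy as np
import pytest

from thromboseg import (
    AttentionMap,
    BiCLSTMHead,
    ConvLSTMCell,
    ConvLSTMState,
    HeadConfig,
    PairSequence,
    ResidualBlock,
    TrainConfig,
    convlstm_step,
    focal_loss,
    predict,
    run_bidirectional,
    train_head,
)
from thromboseg.nn import Tensor


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def scalar_lstm_step(x, h, c, w, peephole):
    """Brute-force scalar LSTM cell: the 1x1-kernel/1-channel oracle."""
    i = sigmoid(w["xi"] * x + w["hi"] * h + (w["ci"] * c if peephole else 0) + w["bi"])
    f = sigmoid(w["xf"] * x + w["hf"] * h + (w["cf"] * c if peephole else 0) + w["bf"])
    g = np.tanh(w["xg"] * x + w["hg"] * h + w["bg"])
    c_new = f * c + i * g
    o = sigmoid(w["xo"] * x + w["ho"] * h + (w["co"] * c_new if peephole else 0) + w["bo"])
    return o * np.tanh(c_new), c_new


def zeroed_cell(in_ch=1, filters=2, k=3, peephole=False):
    cell = ConvLSTMCell(in_ch, filters, k, peephole=peephole, rng=0)
    for p in cell.parameters():
        p.data[:] = 0.0
    return cell


class TestConvLSTMStep:
    def test_zero_weights_zero_state_fixed_point(self):
        cell = zeroed_cell()
        st = convlstm_step(np.zeros((1, 1, 4, 4)), None, cell)
        assert np.all(st.h.data == 0) and np.all(st.c.data == 0)

    def test_zero_weights_constant_cell_closed_form(self):
        """sigma(0)=0.5 gates: C_t = 0.5 c, H_t = 0.5 tanh(0.5 c)."""
        cell = zeroed_cell()
        c = 0.8
        state = ConvLSTMState(
            Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.full((1, 2, 4, 4), c))
        )
        st = convlstm_step(np.zeros((1, 1, 4, 4)), state, cell)
        assert np.allclose(st.c.data, 0.5 * c, atol=1e-12)
        assert np.allclose(st.h.data, 0.5 * np.tanh(0.5 * c), atol=1e-12)

    @pytest.mark.parametrize("peephole", [False, True])
    def test_matches_scalar_cell_oracle(self, peephole):
        """1x1 kernels, 1 channel, 1 pixel == a hand-rolled scalar LSTM."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            cell = ConvLSTMCell(1, 1, 1, peephole=peephole, rng=rng)
            w = {}
            for gate in "ifog":
                w[f"x{gate}"] = float(rng.normal())
                w[f"h{gate}"] = float(rng.normal())
                w[f"b{gate}"] = float(rng.normal())
                getattr(cell, f"w_x{gate}").data[:] = w[f"x{gate}"]
                getattr(cell, f"w_h{gate}").data[:] = w[f"h{gate}"]
                getattr(cell, f"b_{gate}").data[:] = w[f"b{gate}"]
            if peephole:
                for gate in "ifo":
                    w[f"c{gate}"] = float(rng.normal())
                    getattr(cell, f"w_c{gate}").data[:] = w[f"c{gate}"]
            w["bi"], w["bf"], w["bo"], w["bg"] = w["bi"], w["bf"], w["bo"], w["bg"]
            x, h, c = rng.normal(size=3)
            state = ConvLSTMState(
                Tensor(np.full((1, 1, 1, 1), h)), Tensor(np.full((1, 1, 1, 1), c))
            )
            st = cell.step(Tensor(np.full((1, 1, 1, 1), x)), state)
            h_exp, c_exp = scalar_lstm_step(x, h, c, w, peephole)
            assert abs(st.h.data.item() - h_exp) < 1e-6
            assert abs(st.c.data.item() - c_exp) < 1e-6

    def test_hidden_state_bounded(self):
        """|H| < 1 always: o in (0,1) and |tanh(C)| < 1."""
        rng = np.random.default_rng(7)
        cell = ConvLSTMCell(2, 3, 3, peephole=False, rng=rng)
        state = None
        for _ in range(6):
            state = cell.step(Tensor(rng.normal(0, 5, size=(1, 2, 6, 6))), state)
            assert np.all(np.abs(state.h.data) < 1.0)

    def test_shape_mismatch_errors(self):
        cell = ConvLSTMCell(2, 3, 3, rng=0)
        with pytest.raises(ValueError, match="channels"):
            cell.step(Tensor(np.zeros((1, 5, 4, 4))))


class TestBidirectional:
    def _cells(self, seed=0, in_ch=2, filters=3):
        rng = np.random.default_rng(seed)
        return (
            ConvLSTMCell(in_ch, filters, 3, peephole=True, rng=rng),
            ConvLSTMCell(in_ch, filters, 3, peephole=True, rng=rng),
        )

    def test_empty_sequence_errors(self):
        f, b = self._cells()
        with pytest.raises(ValueError, match="empty"):
            run_bidirectional([], f, b)

    def test_length_one_symmetry(self):
        f, b = self._cells()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 2, 5, 5)))
        out = run_bidirectional([x], f, b, fusion_mode="sum")
        expected = f.step(x).h.data + b.step(x).h.data
        assert np.allclose(out[0].data, expected, atol=1e-12)

    def test_concat_doubles_channels(self):
        f, b = self._cells(filters=4)
        seq = [Tensor(np.zeros((1, 2, 5, 5))) for _ in range(3)]
        out = run_bidirectional(seq, f, b, fusion_mode="concat")
        assert out[0].shape == (1, 8, 5, 5)
        assert len(out) == len(seq)

    def test_direction_swap_reverses_outputs(self):
        """Reversing the sequence and swapping cells reverses sum-fused outputs."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            f, b = self._cells(seed=trial)
            seq = [Tensor(rng.normal(size=(1, 2, 4, 4))) for _ in range(5)]
            fwd = run_bidirectional(seq, f, b, fusion_mode="sum")
            swapped = run_bidirectional(seq[::-1], b, f, fusion_mode="sum")
            for a, c in zip(fwd, swapped[::-1]):
                assert np.abs(a.data - c.data).max() < 1e-6


class TestResidualBlock:
    def test_zero_f_path_is_identity_for_nonnegative_64ch(self):
        rng = np.random.default_rng(0)
        block = ResidualBlock(64, 64, rng)
        for name in ("conv1", "conv2"):
            getattr(block, name).weight.data[:] = 0.0
            getattr(block, name).bias.data[:] = 0.0
        x = Tensor(np.abs(rng.normal(size=(1, 64, 5, 5))))
        out = block(x)
        assert np.allclose(out.data, x.data, atol=1e-12)

    def test_channel_projection_shape(self):
        block = ResidualBlock(2, 64, np.random.default_rng(1))
        out = block(Tensor(np.random.default_rng(2).normal(size=(1, 2, 7, 9))))
        assert out.shape == (1, 64, 7, 9)

    def test_matches_direct_convolution_oracle(self):
        """Residual output reproduced by explicit loops over the definition."""
        rng = np.random.default_rng(4)
        block = ResidualBlock(1, 2, rng).eval()
        x = rng.normal(size=(5, 5))

        def direct_conv(img_c, w):  # img_c: (C,5,5), w: (O,C,3,3)
            C, H, W = img_c.shape
            out = np.zeros((w.shape[0], H, W))
            xp = np.pad(img_c, ((0, 0), (1, 1), (1, 1)))
            for o in range(w.shape[0]):
                for r in range(H):
                    for c in range(W):
                        out[o, r, c] = np.sum(xp[:, r : r + 3, c : c + 3] * w[o])
            return out

        def bn_eval(t, bn):
            return (t - bn.running_mean[0]) / np.sqrt(bn.running_var[0] + bn.eps) * (
                bn.gamma.data[0]
            ) + bn.beta.data[0]

        f = bn_eval(
            direct_conv(x[None], block.conv1.weight.data)
            + block.conv1.bias.data[:, None, None],
            block.bn1,
        )
        f = np.maximum(f, 0)
        f = bn_eval(
            direct_conv(f, block.conv2.weight.data) + block.conv2.bias.data[:, None, None],
            block.bn2,
        )
        proj = (
            x[None] * block.project.weight.data[:, 0]  # 1x1 kernels
            + block.project.bias.data[:, None, None]
        )
        expected = np.maximum(proj + f, 0)
        got = block(Tensor(x[None, None])).data[0]
        assert np.abs(got - expected).max() < 1e-5


class TestFocalLoss:
    def test_gamma0_alpha_half_is_half_bce(self, rng):
        p = rng.uniform(0.05, 0.95, size=(8, 8))
        y = (rng.random((8, 8)) < 0.3).astype(float)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert abs(focal_loss(p, y, alpha=0.5, gamma=0.0) - 0.5 * bce) < 1e-6

    def test_perfect_prediction_near_zero(self):
        y = np.zeros((6, 6))
        y[2:4, 2:4] = 1
        assert focal_loss(y.copy(), y, alpha=0.25, gamma=2.0) <= 1e-5

    def test_single_pixel_closed_form(self):
        loss = focal_loss(np.array([[0.9]]), np.array([[1.0]]), alpha=0.25, gamma=2.0)
        assert abs(loss - (-0.25 * 0.01 * np.log(0.9))) < 1e-9

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            focal_loss(np.ones((2, 2)) * 0.5, np.ones((3, 3)))

    def test_tensor_path_matches_array_path(self, rng):
        p = rng.uniform(0.01, 0.99, size=(5, 5))
        y = (rng.random((5, 5)) < 0.5).astype(float)
        assert focal_loss(Tensor(p, True), y).item() == pytest.approx(
            focal_loss(p, y), abs=1e-12
        )


def make_sequence(rng, n=5, size=8):
    pairs = [
        (
            rng.integers(0, 255, (size, size)).astype(np.uint8),
            AttentionMap(rng.random((size, size))),
        )
        for _ in range(n)
    ]
    return PairSequence(pairs=pairs, target_index=(n - 1) // 2, padding_flags=[False] * n)


def tiny_cfg(**kw):
    base = dict(residual_filters=4, clstm_filters=4, fusion_filters=4)
    base.update(kw)
    return HeadConfig(**base)


class TestPredict:
    def test_zero_final_conv_gives_half_probability_and_tie_rule(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=0)
        model.out_conv.weight.data[:] = 0.0
        model.out_conv.bias.data[:] = 0.0
        probs, mask = predict(model, make_sequence(rng), allow_untrained=True)
        assert np.allclose(probs, 0.5)
        assert np.all(mask == 1)  # >= threshold: ties go to foreground

    def test_probabilities_in_unit_interval(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=1)
        probs, _ = predict(model, make_sequence(rng), allow_untrained=True)
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        assert probs.shape == (8, 8)

    def test_untrained_model_errors(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=1)
        with pytest.raises(RuntimeError, match="untrained|not trained"):
            predict(model, make_sequence(rng))

    def test_all_slices_scope_returns_per_position_maps(self, rng):
        model = BiCLSTMHead(tiny_cfg(output_scope="all_slices"), rng=1)
        out = model(make_sequence(rng, n=3))
        assert isinstance(out, list) and len(out) == 3

    def test_output_shape_follows_input_shape(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=1)
        probs, _ = predict(model, make_sequence(rng, size=11), allow_untrained=True)
        assert probs.shape == (11, 11)


class TestTrainHead:
    def _samples(self, rng, n=3):
        samples = []
        for _ in range(n):
            seq = make_sequence(rng)
            gt = np.zeros((8, 8), np.uint8)
            gt[2:5, 2:5] = 1
            samples.append((seq, gt))
        return samples

    def test_empty_training_set_errors(self):
        model = BiCLSTMHead(tiny_cfg(), rng=0)
        with pytest.raises(ValueError, match="empty"):
            train_head(model, [], TrainConfig(steps=1))

    def test_zero_lr_leaves_parameters_unchanged(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        train_head(model, self._samples(rng), TrainConfig(lr=0.0, steps=3, seed=0))
        after = model.state_dict()
        trainable = dict(model.named_parameters())
        assert all(
            np.array_equal(before[k], after[k]) for k in trainable
        )

    def test_identical_seed_gives_bit_identical_traces(self, rng):
        samples = self._samples(rng)
        _, t1 = train_head(BiCLSTMHead(tiny_cfg(), rng=5), samples, TrainConfig(steps=5, seed=9))
        _, t2 = train_head(BiCLSTMHead(tiny_cfg(), rng=5), samples, TrainConfig(steps=5, seed=9))
        assert t1 == t2

    def test_loss_trace_recorded_per_step(self, rng):
        model = BiCLSTMHead(tiny_cfg(), rng=2)
        _, trace = train_head(model, self._samples(rng), TrainConfig(steps=4, seed=1))
        assert len(trace) == 4 and all(np.isfinite(v) for v in trace)
        assert model.trained
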