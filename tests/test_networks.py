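"""Network building blocks, gradients, and training behavior."""

import numpy as np
import pytest

from imu2seg.body_model import SegmentClass
from imu2seg.dataset_windows import Window
from imu2seg.networks import (
    ConvLayerSpec,
    GRULayer,
    LSTMLayer,
    ModelConfig,
    SequenceModel,
    TrainedModel,
    alignment_forward,
    assignment_forward,
    recurrent_forward,
    softmax,
    train,
)
from imu2seg.networks.layers import Conv1D, ConvBlock
from imu2seg.networks.training import cross_entropy_loss, stereo_l2_loss


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestConv:
    def test_zero_input_zero_bias_gives_zero(self):
        blk = ConvBlock(2, 4, 3, _rng())
        out = blk.forward(np.zeros((3, 20, 2), dtype=np.float32),
                          training=True)
        assert np.allclose(out, 0.0)

    def test_delta_kernel_identity(self):
        """A centered delta kernel with BN bypassed copies the valid region."""
        conv = Conv1D(1, 1, 3, _rng())
        conv.params["K"][:] = 0.0
        conv.params["K"][1, 0, 0] = 1.0
        conv.params["b"][:] = 0.0
        x = _rng(1).normal(size=(2, 30, 1))
        out = conv.forward(x)
        assert np.allclose(out, x[:, 1:-1], atol=1e-7)

    def test_valid_length_arithmetic(self):
        cfg = ModelConfig(task="assignment",
                          conv=[ConvLayerSpec(9, 4)] * 4,
                          recurrent_units=[8])
        model = SequenceModel(cfg)
        assert model.output_length(128) == 128 - 4 * 8  # 96

    def test_too_short_sequence_rejected(self):
        conv = Conv1D(1, 1, 9, _rng())
        with pytest.raises(ValueError):
            conv.forward(np.zeros((1, 4, 1), dtype=np.float32))


class TestRecurrent:
    def test_zero_weights_keep_zero_state(self):
        for kind, gates in (("gru", 3), ("lstm", 4)):
            H = 4
            w = {"Wx": np.zeros((2, gates * H)), "Wh": np.zeros((H, gates * H)),
                 "b": np.zeros(gates * H)}
            out = recurrent_forward(np.ones((2, 5, 2)), kind, w)
            assert np.allclose(out, 0.0)

    def test_length_one_equals_single_step(self, rng):
        layer = GRULayer(3, 5, _rng(2))
        x = rng.normal(size=(4, 1, 3)).astype(np.float32)
        out = layer.forward(x)
        w = layer.params
        H = 5
        z = 1 / (1 + np.exp(-(x[:, 0] @ w["Wx"][:, :H] + w["b"][:H])))
        # h_prev = 0 so the candidate reduces to tanh of the input part
        n = np.tanh(x[:, 0] @ w["Wx"][:, 2 * H:] + w["b"][2 * H:])
        assert np.allclose(out[:, 0], z * n, atol=1e-6)

    def test_gru_matches_manual_recurrence(self):
        """1-unit GRU over 3 scalar steps vs a step-by-step hand computation."""
        w = {"Wx": np.array([[0.5, -0.3, 0.8]]),
             "Wh": np.array([[0.2, 0.4, -0.6]]),
             "b": np.array([0.1, -0.2, 0.05])}
        x = np.array([[[1.0], [-0.5], [0.25]]])
        out = recurrent_forward(x, "gru", w)
        sig = lambda v: 1 / (1 + np.exp(-v))
        h = 0.0
        expected = []
        for xv in (1.0, -0.5, 0.25):
            z = sig(0.5 * xv + 0.2 * h + 0.1)
            r = sig(-0.3 * xv + 0.4 * h - 0.2)
            n = np.tanh(0.8 * xv + r * (-0.6 * h) + 0.05)
            h = (1 - z) * h + z * n
            expected.append(h)
        assert np.allclose(out[0, :, 0], expected, atol=1e-10)

    def test_lstm_matches_manual_recurrence(self):
        w = {"Wx": np.array([[0.4, 0.3, -0.7, 0.6]]),
             "Wh": np.array([[-0.2, 0.5, 0.1, 0.3]]),
             "b": np.array([0.0, 1.0, -0.1, 0.2])}
        x = np.array([[[0.8], [-0.4]]])
        out = recurrent_forward(x, "lstm", w)
        sig = lambda v: 1 / (1 + np.exp(-v))
        h = c = 0.0
        expected = []
        for xv in (0.8, -0.4):
            i = sig(0.4 * xv - 0.2 * h + 0.0)
            f = sig(0.3 * xv + 0.5 * h + 1.0)
            g = np.tanh(-0.7 * xv + 0.1 * h - 0.1)
            o = sig(0.6 * xv + 0.3 * h + 0.2)
            c = f * c + i * g
            h = o * np.tanh(c)
            expected.append(h)
        assert np.allclose(out[0, :, 0], expected, atol=1e-10)


class TestHeads:
    def test_softmax_uniform_for_equal_logits(self):
        p = softmax(np.zeros((1, 7)))
        assert np.allclose(p, 1 / 7)

    def test_softmax_closed_form(self):
        p = softmax(np.array([[1.0, 0, 0, 0, 0, 0, 0]]))
        assert p[0, 0] == pytest.approx(np.e / (np.e + 6), abs=1e-6)
        assert p.argmax() == 0

    def test_softmax_normalized_on_random_inputs(self, rng):
        logits = rng.normal(size=(1000, 7)) * 5
        p = softmax(logits)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_assignment_forward_probabilities(self):
        cfg = ModelConfig.tiny("assignment", conv=[ConvLayerSpec(9, 8)],
                               recurrent_units=[8])
        model = SequenceModel(cfg)
        w = Window(np.zeros((128, 6), dtype=np.float32),
                   SegmentClass.Pelvis, np.zeros(3), "s")
        p = assignment_forward(w, model)
        assert p.shape == (7,) and abs(p.sum() - 1) < 1e-6

    def test_alignment_zero_head_decodes_to_identity(self):
        cfg = ModelConfig.tiny("alignment", conv=[ConvLayerSpec(9, 8)],
                               recurrent_units=[8])
        model = SequenceModel(cfg)
        model.head.params["W"][:] = 0.0
        model.head.params["b"][:] = 0.0
        w = Window(np.zeros((128, 6), dtype=np.float32),
                   SegmentClass.Pelvis, np.zeros(3), "s")
        q = alignment_forward(w, model, decode=True)
        assert np.allclose(q.wxyz, [1, 0, 0, 0])

    def test_decoded_quaternions_unit_norm(self, rng):
        from imu2seg.rotmath import stereo_to_quat_array
        s = rng.normal(size=(1000, 3)) * 2.0
        q = stereo_to_quat_array(s)
        assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)

    def test_task_mismatch_rejected(self):
        cfg = ModelConfig.tiny("alignment", conv=[ConvLayerSpec(9, 8)],
                               recurrent_units=[8])
        model = SequenceModel(cfg)
        w = Window(np.zeros((128, 6), dtype=np.float32),
                   SegmentClass.Pelvis, np.zeros(3), "s")
        with pytest.raises(ValueError):
            assignment_forward(w, model)


def _float64_model(task, rtype, seed=3):
    cfg = ModelConfig(task=task, conv=[ConvLayerSpec(3, 4)],
                      recurrent_type=rtype, recurrent_units=[4],
                      noise_sigma=(0,) * 6, input_keep=1.0, seed=seed)
    m = SequenceModel(cfg, n_channels=2)
    for layer, name in m.param_handles():
        layer.params[name] = layer.params[name].astype(np.float64)
    for blk in m.blocks:
        blk.bn.running_mean = blk.bn.running_mean.astype(np.float64)
        blk.bn.running_var = blk.bn.running_var.astype(np.float64)
    return m


@pytest.mark.parametrize("task,rtype", [("assignment", "gru"),
                                        ("alignment", "lstm")])
def test_full_network_gradient_check(task, rtype):
    """Backprop through conv+BN+ReLU+RNN+head matches finite differences."""
    m = _float64_model(task, rtype)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 12, 2))
    if task == "assignment":
        y = rng.integers(0, 7, size=5)
        lossfn = lambda out: cross_entropy_loss(out, y)
    else:
        t = rng.normal(size=(5, 3)) * 0.3
        lossfn = lambda out: stereo_l2_loss(out, t)

    def loss_at():
        return lossfn(m.forward(X, training=True))

    _, grad = loss_at()
    m.backward(grad)
    for layer, name in m.param_handles():
        g = layer.grads[name]
        p = layer.params[name]
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            lp, _ = loss_at()
            p[idx] = orig - eps
            lm, _ = loss_at()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(g[idx]), 1e-8)
            assert abs(num - g[idx]) / denom < 2e-5, (type(layer).__name__, name)


# ----------------------------------------------------------------------
# training behavior on a trivially separable problem
# ----------------------------------------------------------------------

def _separable_split(n_per_class=100, seed=0):
    """Two classes with disjoint constant channels; third subject held out."""
    rng = np.random.default_rng(seed)
    wins = []
    for subj in ("a", "b", "t"):
        for cls, chan in ((SegmentClass.Pelvis, 0), (SegmentClass.LeftFoot, 3)):
            for _ in range(n_per_class // 2):
                x = rng.normal(0, 0.05, size=(128, 6)).astype(np.float32)
                x[:, chan] += 1.0
                wins.append(Window(x, cls, np.zeros(3), subj))
    from imu2seg.dataset_windows import loso_split
    return loso_split(wins, "t", seed=seed)


def _tiny_cfg(**kw):
    base = dict(conv=[ConvLayerSpec(9, 8)], recurrent_units=[8],
                max_epochs=5, patience=10, seed=1, batch_size=50,
                noise_sigma=(0,) * 6, input_keep=1.0)
    base.update(kw)
    return ModelConfig.tiny("assignment", **base)


class TestTraining:
    def test_separable_problem_reaches_full_train_accuracy(self):
        split = _separable_split()
        tm = train(_tiny_cfg(max_epochs=50, patience=50, learning_rate=3e-3),
                   split)
        from imu2seg.dataset_windows import stack_windows
        data = stack_windows(split.train)
        pred = tm.model.predict(data["X"]).argmax(axis=1)
        assert np.mean(pred == data["y"]) == 1.0

    def test_seed_determinism_bitwise(self):
        split = _separable_split()
        h1 = train(_tiny_cfg(max_epochs=3), split).history
        h2 = train(_tiny_cfg(max_epochs=3), split).history
        assert h1 == h2  # bit-identical floats

    def test_full_batch_loss_decreases(self):
        split = _separable_split()
        cfg = _tiny_cfg(max_epochs=8, batch_size=10_000)  # full batch
        tm = train(cfg, split)
        losses = [h["train_loss"] for h in tm.history]
        assert all(b <= a + 1e-8 for a, b in zip(losses, losses[1:]))

    def test_warm_start_lowers_initial_val_loss(self):
        split = _separable_split()
        cold = train(_tiny_cfg(max_epochs=10, patience=10), split)
        warm = train(_tiny_cfg(max_epochs=2), split, warm_start=cold)
        assert warm.history[0]["val_loss"] <= cold.history[0]["val_loss"]
        assert warm.provenance.startswith("warm-started")

    def test_warm_start_shape_mismatch_rejected(self):
        split = _separable_split()
        cold = train(_tiny_cfg(max_epochs=1), split)
        bigger = _tiny_cfg(max_epochs=1, recurrent_units=[16])
        with pytest.raises(ValueError):
            train(bigger, split, warm_start=cold)

    def test_checkpoint_round_trip(self, tmp_path):
        split = _separable_split()
        tm = train(_tiny_cfg(max_epochs=2), split)
        tm.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        from imu2seg.dataset_windows import stack_windows
        X = stack_windows(split.test)["X"]
        assert np.allclose(back.model.predict(X), tm.model.predict(X),
                           atol=1e-7)
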