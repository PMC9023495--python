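import dataclasses

import numpy as np
import pytest

from compressnet.network import (
    LayerSpec, NetworkSpec, SpecError, backward, build_network, copy_model,
    desk_student, desk_teacher, forward, load_checkpoint, parameter_count,
    replace_head, save_checkpoint, student_reference, teacher_reference,
)
from compressnet.network.ops import cross_entropy, softmax

from conftest import plain_conv_spec


def loop_conv2d(x, W, stride, pad):
    """Explicit-loop cross-correlation oracle (single image, CHW)."""
    cin, h, w = x.shape
    cout, _, k, _ = W.shape
    xp = np.zeros((cin, h + 2 * pad, w + 2 * pad))
    xp[:, pad:pad + h, pad:pad + w] = x
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    out = np.zeros((cout, ho, wo))
    for o in range(cout):
        for i in range(ho):
            for j in range(wo):
                patch = xp[:, i * stride:i * stride + k, j * stride:j * stride + k]
                out[o, i, j] = np.sum(patch * W[o])
    return out


class TestSpecs:
    def test_student_reference_has_17_prunable_blocks(self):
        assert student_reference().n_prunable == 17

    def test_teacher_reference_builds(self):
        spec = teacher_reference()
        assert spec.hidden_dim == 1280
        assert spec.n_prunable > 0

    def test_desk_specs_share_hidden_dim(self):
        assert desk_student().hidden_dim == desk_teacher().hidden_dim

    def test_channel_chain_validation(self):
        with pytest.raises(SpecError):
            NetworkSpec((
                LayerSpec("c", "conv", 4, kernel=3),
                LayerSpec("d", "depthwise_conv", 5, kernel=3),  # 5 != 4
                LayerSpec("hidden", "fully_connected", 4, has_norm=False, bias=True),
                LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True),
            ), hidden_dim=4, n_classes=2)

    def test_hidden_layer_required(self):
        with pytest.raises(SpecError):
            NetworkSpec((
                LayerSpec("c", "conv", 4, kernel=3),
                LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True),
            ), hidden_dim=4, n_classes=2)

    def test_residual_feeder_not_prunable(self):
        with pytest.raises(SpecError):
            NetworkSpec((
                LayerSpec("a", "conv", 4, kernel=3, prunable=True),
                LayerSpec("b", "conv", 4, kernel=3, residual_from=0),
                LayerSpec("hidden", "fully_connected", 4, has_norm=False, bias=True),
                LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True),
            ), hidden_dim=4, n_classes=2)


class TestBuild:
    def test_deterministic(self):
        spec = desk_student(n_classes=5, hidden_dim=16, input_size=32)
        a, b = build_network(spec, seed=9), build_network(spec, seed=9)
        for pa, pb in zip(a.params, b.params):
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])

    def test_seed_changes_weights(self):
        spec = desk_student(n_classes=5, hidden_dim=16, input_size=32)
        a, b = build_network(spec, seed=1), build_network(spec, seed=2)
        assert not np.array_equal(a.params[0]["W"], b.params[0]["W"])

    def test_tiny_desk_smoke(self, rng):
        spec = desk_student(n_classes=10, hidden_dim=32, input_size=64,
                            block_cfg=((8, 6, 2), (12, 8, 2), (16, 12, 1)))
        assert spec.n_prunable == 3
        m = build_network(spec, seed=0)
        x = rng.uniform(0, 1, (2, 3, 64, 64)).astype(np.float32)
        res = forward(m, x)
        assert res.logits.shape == (2, 10)
        assert res.hidden.shape == (2, 32)


class TestForward:
    def test_softmax_uniform_for_zeroed_head(self, micro_student, rng):
        m = micro_student
        m.params[-1]["W"][:] = 0
        m.params[-1]["b"][:] = 0
        res = forward(m, rng.uniform(0, 1, (3, 3, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(res.softmax, 0.25, atol=1e-6)

    def test_softmax_simplex_extreme_logits(self):
        s = softmax(np.array([[1e4, -1e4, 0.0], [-1e4, -1e4, -1e4]]))
        assert np.all(s >= 0)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)

    def test_captured_feature_map_shapes(self, micro_student, rng):
        x = rng.uniform(0, 1, (2, 3, 16, 16)).astype(np.float32)
        res = forward(micro_student, x, capture={0, 1, 2})
        spec = micro_student.spec
        sizes = spec.spatial_sizes()
        for t in (0, 1, 2):
            assert res.feature_maps[t].shape == (
                2, spec.layers[t].out_filters, sizes[t], sizes[t])

    def test_eval_mode_deterministic(self, micro_student, rng):
        x = rng.uniform(0, 1, (2, 3, 16, 16)).astype(np.float32)
        a = forward(micro_student, x, training=False).logits
        b = forward(micro_student, x, training=False).logits
        np.testing.assert_array_equal(a, b)

    def test_single_conv_matches_loop_oracle(self, rng):
        spec = NetworkSpec((
            LayerSpec("c", "conv", 4, kernel=3, has_norm=False, activation="linear"),
            LayerSpec("hidden", "fully_connected", 4, has_norm=False, bias=True),
            LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True,
                      activation="linear"),
        ), hidden_dim=4, n_classes=2, input_size=5)
        m = build_network(spec, seed=0, dtype=np.float64)
        x = rng.normal(size=(1, 3, 5, 5))
        got = forward(m, x, capture={0}).feature_maps[0][0]
        want = loop_conv2d(x[0], m.params[0]["W"], stride=1, pad=1)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_shape_mismatch_raises(self, micro_student, rng):
        bad = rng.uniform(0, 1, (2, 4, 16, 16)).astype(np.float32)
        with pytest.raises(ValueError):
            forward(micro_student, bad)


class TestBackward:
    def test_gradients_match_finite_differences(self, rng):
        """Combined check over conv/depthwise/pointwise/dense on a toy net."""
        from compressnet.network.specs import LayerSpec, NetworkSpec
        layers = (
            LayerSpec("pw", "pointwise_conv", 4),
            LayerSpec("dw", "depthwise_conv", 4, kernel=3, stride=2),
            LayerSpec("proj", "pointwise_conv", 3, activation="linear"),
            LayerSpec("hidden", "fully_connected", 5, has_norm=False, bias=True),
            LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True,
                      activation="linear"),
        )
        spec = NetworkSpec(layers, hidden_dim=5, n_classes=2, input_size=8)
        m = build_network(spec, seed=0, dtype=np.float64)
        x = np.random.default_rng(1).uniform(0, 1, (3, 3, 8, 8))
        lab = np.array([0, 1, 0])

        def loss_fn():
            r = forward(m, x, training=False)
            z = r.logits - r.logits.max(axis=1, keepdims=True)
            return float(np.mean(np.log(np.exp(z).sum(axis=1)) - z[np.arange(3), lab]))

        res = forward(m, x, training=False, record=True)
        _, dlogits = cross_entropy(res.logits, lab)
        grads = backward(m, res, dlogits)
        checked = 0
        for i, p in enumerate(m.params):
            for key in ("W", "b", "gamma", "beta"):
                if key not in p:
                    continue
                arr = p[key]
                flat = arr.reshape(-1)
                for j in range(0, flat.size, max(1, flat.size // 5)):
                    eps = 1e-6
                    old = flat[j]
                    flat[j] = old + eps
                    lp = loss_fn()
                    flat[j] = old - eps
                    lm = loss_fn()
                    flat[j] = old
                    num = (lp - lm) / (2 * eps)
                    ana = grads[i][key].reshape(-1)[j]
                    assert abs(num - ana) / max(1e-8, abs(num) + abs(ana)) < 1e-4
                    checked += 1
        assert checked > 20

    def test_residual_gradients(self, rng):
        spec = desk_teacher(n_classes=3, hidden_dim=8, input_size=16, widths=(4, 6))
        m = build_network(spec, seed=5, dtype=np.float64)
        x = np.random.default_rng(2).uniform(0, 1, (2, 3, 16, 16))
        lab = np.array([0, 1])
        res = forward(m, x, training=False, record=True)
        _, dl = cross_entropy(res.logits, lab)
        grads = backward(m, res, dl)

        def loss_fn():
            r = forward(m, x, training=False)
            z = r.logits - r.logits.max(axis=1, keepdims=True)
            return float(np.mean(np.log(np.exp(z).sum(axis=1)) - z[np.arange(2), lab]))

        arr = m.params[1]["W"]  # conv inside the first residual block
        for j in (0, arr.size // 2, arr.size - 1):
            eps = 1e-6
            old = arr.reshape(-1)[j]
            arr.reshape(-1)[j] = old + eps
            lp = loss_fn()
            arr.reshape(-1)[j] = old - eps
            lm = loss_fn()
            arr.reshape(-1)[j] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[1]["W"].reshape(-1)[j]
            assert abs(num - ana) / max(1e-8, abs(num) + abs(ana)) < 1e-4


class TestParameterCount:
    def test_plain_conv_count(self):
        spec = NetworkSpec((
            LayerSpec("c", "conv", 8, kernel=3, has_norm=False, activation="linear"),
            LayerSpec("hidden", "fully_connected", 4, has_norm=False, bias=True),
            LayerSpec("head", "fully_connected", 2, has_norm=False, bias=True,
                      activation="linear"),
        ), hidden_dim=4, n_classes=2, in_channels=4, input_size=8)
        m = build_network(spec, seed=0)
        # conv: 8*4*3*3 = 288; hidden: 4*8+4; head: 2*4+2
        assert parameter_count(m) == 288 + 36 + 10
        m.params[0]["W"] = m.params[0]["W"][:4]  # crude slice for the count only
        assert m.params[0]["W"].size == 144

    def test_only_prunable_counts_filter_banks(self, micro_student):
        spec = micro_student.spec
        want = sum(micro_student.params[i]["W"].size for i in spec.prunable_layers())
        assert parameter_count(micro_student, only_prunable=True) == want

    def test_halving_arithmetic_per_layer(self):
        from compressnet.prune import cut_counts
        spec = desk_student()
        for t in spec.prunable_layers():
            c = spec.layers[t].out_filters
            removed, reserved = cut_counts(c, 0.5)
            assert reserved == c // 2  # C - ceil(C/2) = floor(C/2)


class TestStatePlumbing:
    def test_checkpoint_roundtrip(self, micro_student, tmp_path):
        micro_student.cut_history.append((1, [0, 2]))
        path = tmp_path / "m.ckpt"
        save_checkpoint(micro_student, path)
        back = load_checkpoint(path)
        assert back.spec == micro_student.spec
        assert back.cut_history == [(1, [0, 2])]
        for pa, pb in zip(micro_student.params, back.params):
            assert set(pa) == set(pb)
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])

    def test_replace_head_preserves_trunk_bitexact(self, micro_student):
        before = [{k: v.copy() for k, v in p.items()} for p in micro_student.params[:-1]]
        new = replace_head(micro_student, n_classes=7, seed=3)
        assert new.spec.n_classes == 7
        assert new.params[-1]["W"].shape == (7, micro_student.spec.hidden_dim)
        for pa, pb in zip(before, new.params[:-1]):
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])

    def test_copy_model_is_deep(self, micro_student):
        c = copy_model(micro_student)
        c.params[0]["W"][:] = 99.0
        assert not np.array_equal(c.params[0]["W"], micro_student.params[0]["W"])
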