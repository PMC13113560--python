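"""Bidirectional inter-modulation fusion: ops, bounds, gradients."""

import numpy as np
import pytest

from cabif.bif_fusion import (
    CabifNet,
    FusionParams,
    fuse_and_classify,
    inter_modulate,
    layer_normalize,
    modulation_signals,
    ModulatedFeatures,
    ModulationSignals,
    NormalizedFeatures,
)
from cabif.calibration import ModalityWeights
from cabif.pipeline import smoothed_cross_entropy


def _params(D=4, H=2, C=3, seed=0, zero=False):
    return FusionParams.initialize(D, C, H=H, seed=seed, zero_init_last=zero)


def _weights(wv):
    return ModalityWeights(cv=0.0, ca=0.0, wv=wv, wa=1.0 - wv)


class TestLayerNormalize:
    def test_two_point_vector_standardizes(self):
        p = _params(D=2)
        n = layer_normalize(np.array([1.0, 3.0]), np.array([0.0, 0.0]), p)
        np.testing.assert_allclose(n.fv_n, [-1.0, 1.0], atol=1e-2)

    def test_constant_vector_maps_to_zero(self):
        p = _params(D=3)
        n = layer_normalize(np.full(3, 5.0), np.full(3, -2.0), p)
        np.testing.assert_allclose(n.fv_n, 0.0, atol=1e-12)
        np.testing.assert_allclose(n.fa_n, 0.0, atol=1e-12)

    def test_affine_gain_and_bias_applied(self):
        p = _params(D=2)
        p.g_v[...] = 2.0
        p.b_v[...] = 1.0
        n = layer_normalize(np.array([1.0, 3.0]), np.zeros(2), p)
        np.testing.assert_allclose(n.fv_n, [-1.0, 3.0], atol=2e-2)


class TestModulationSignals:
    def test_zero_mlp_gives_zero_signals(self, rng):
        p = _params(zero=True)
        for key in ("W1_a2v", "b1_a2v", "W1_v2a", "b1_v2a"):
            getattr(p, key)[...] = 0.0
        n = NormalizedFeatures(fv_n=rng.normal(size=4), fa_n=rng.normal(size=4))
        s = modulation_signals(n, p)
        np.testing.assert_array_equal(s.sv, 0.0)
        np.testing.assert_array_equal(s.sa, 0.0)

    def test_signals_strictly_inside_unit_box(self, rng):
        # realistic scale: inputs are layer-normalized, entries O(1)
        p = _params(D=6, H=3, seed=4)
        n = layer_normalize(rng.normal(size=6), rng.normal(size=6), p)
        s = modulation_signals(n, p)
        assert np.max(np.abs(s.sv)) < 1.0
        assert np.max(np.abs(s.sa)) < 1.0
        # extreme inputs: float tanh saturates but never exceeds the bound
        extreme = NormalizedFeatures(
            fv_n=rng.normal(size=6) * 1e3, fa_n=rng.normal(size=6) * 1e3
        )
        s = modulation_signals(extreme, p)
        assert np.max(np.abs(s.sv)) <= 1.0
        assert np.max(np.abs(s.sa)) <= 1.0

    def test_hand_computed_tiny_mlp(self):
        # D=2, H=1: Linear -> SiLU -> Linear -> tanh by hand
        p = _params(D=2, H=1, C=2)
        p.W1_a2v[...] = [[1.0, -1.0]]
        p.b1_a2v[...] = 0.5
        p.W2_a2v[...] = [[2.0], [-0.5]]
        p.b2_a2v[...] = [0.1, -0.1]
        fa_n = np.array([0.3, -0.2])
        h = 1.0 * 0.3 + (-1.0) * (-0.2) + 0.5  # = 1.0
        u = h / (1 + np.exp(-h))
        expected_sv = np.tanh([2.0 * u + 0.1, -0.5 * u - 0.1])
        n = NormalizedFeatures(fv_n=np.zeros(2), fa_n=fa_n)
        s = modulation_signals(n, p)
        np.testing.assert_allclose(s.sv, expected_sv, rtol=1e-12)


class TestInterModulate:
    def test_zero_weight_leaves_visual_untouched(self, rng):
        n = NormalizedFeatures(fv_n=rng.normal(size=4), fa_n=rng.normal(size=4))
        s = ModulationSignals(sv=rng.uniform(-1, 1, 4), sa=rng.uniform(-1, 1, 4))
        m = inter_modulate(n, s, _weights(0.0))
        np.testing.assert_array_equal(m.fv_cm, n.fv_n)

    def test_zero_signals_identity(self, rng):
        n = NormalizedFeatures(fv_n=rng.normal(size=4), fa_n=rng.normal(size=4))
        s = ModulationSignals(sv=np.zeros(4), sa=np.zeros(4))
        m = inter_modulate(n, s, _weights(0.37))
        np.testing.assert_array_equal(m.fv_cm, n.fv_n)
        np.testing.assert_array_equal(m.fa_cm, n.fa_n)

    def test_hand_arithmetic(self):
        n = NormalizedFeatures(fv_n=np.zeros(2), fa_n=np.zeros(2))
        s = ModulationSignals(sv=np.zeros(2), sa=np.array([0.5, -0.5]))
        m = inter_modulate(n, s, _weights(0.8))
        np.testing.assert_allclose(m.fv_cm, [0.4, -0.4])

    def test_crossed_variant_swaps_signal_routing(self, rng):
        n = NormalizedFeatures(fv_n=rng.normal(size=3), fa_n=rng.normal(size=3))
        s = ModulationSignals(sv=rng.uniform(-1, 1, 3), sa=rng.uniform(-1, 1, 3))
        w = _weights(0.6)
        pub = inter_modulate(n, s, w, variant="as_published")
        crossed = inter_modulate(n, s, w, variant="crossed")
        np.testing.assert_allclose(pub.fv_cm, n.fv_n + 0.6 * s.sa)
        np.testing.assert_allclose(crossed.fv_cm, n.fv_n + 0.6 * s.sv)

    def test_unknown_variant_rejected(self, rng):
        n = NormalizedFeatures(fv_n=np.zeros(2), fa_n=np.zeros(2))
        s = ModulationSignals(sv=np.zeros(2), sa=np.zeros(2))
        with pytest.raises(ValueError, match="variant"):
            inter_modulate(n, s, _weights(0.5), variant="sideways")

    def test_bounded_perturbation(self, rng):
        # ||f_cm - f_n||_inf <= w because |signal| < 1
        p = _params(D=8, H=4, seed=1)
        n = NormalizedFeatures(fv_n=rng.normal(size=8), fa_n=rng.normal(size=8))
        s = modulation_signals(n, p)
        for wv in (0.0, 0.3, 0.9, 1.0):
            m = inter_modulate(n, s, _weights(wv))
            assert np.max(np.abs(m.fv_cm - n.fv_n)) <= wv
            assert np.max(np.abs(m.fa_cm - n.fa_n)) <= 1.0 - wv


class TestFuseAndClassify:
    def test_fused_vector_has_double_length(self, rng):
        p = FusionParams.initialize(512, 30, seed=0)
        m = ModulatedFeatures(
            fv_cm=rng.normal(size=512), fa_cm=rng.normal(size=512)
        )
        out = fuse_and_classify(m, p)
        assert out.phi.shape == (1024,)

    def test_null_head_gives_uniform_prediction(self, rng):
        p = _params(D=4, C=5)
        p.W_head[...] = 0.0
        p.b_head[...] = 0.0
        m = ModulatedFeatures(fv_cm=rng.normal(size=4), fa_cm=rng.normal(size=4))
        out = fuse_and_classify(m, p)
        np.testing.assert_array_equal(out.z_fuse, 0.0)
        assert out.y_hat == 0  # lowest-index tie-break
        assert out.fused_confidence == pytest.approx(1 / 5)

    def test_head_matches_manual_matvec(self):
        p = _params(D=2, C=2)
        p.g_f[...] = 1.0
        p.b_f[...] = 0.0
        p.W_head[...] = [[1.0, 0.0, -1.0, 2.0], [0.5, 0.5, 0.5, 0.5]]
        p.b_head[...] = [0.1, -0.1]
        m = ModulatedFeatures(fv_cm=np.array([1.0, 2.0]), fa_cm=np.array([3.0, 4.0]))
        out = fuse_and_classify(m, p)
        expected = p.W_head @ out.phi + p.b_head
        np.testing.assert_allclose(out.z_fuse, expected, rtol=1e-12)
        assert out.p_fuse.sum() == pytest.approx(1.0, abs=1e-9)


class TestCabifNet:
    def test_batch_equals_per_sample_processing(self, rng):
        D, C, B = 6, 4, 9
        net = CabifNet(D, C, seed=3)
        fv, fa = rng.normal(size=(B, D)), rng.normal(size=(B, D))
        zv, za = rng.normal(size=(B, C)), rng.normal(size=(B, C))
        batched = net.predict(fv, fa, zv, za)
        for i in range(B):
            single = net.predict(fv[i], fa[i], zv[i], za[i])
            np.testing.assert_allclose(single.z_fuse[0], batched.z_fuse[i], atol=1e-5)

    def test_zero_modulation_reduces_to_layernorm_concat(self, rng):
        """With the modulation MLPs' output layers zeroed, the network
        collapses to LayerNorm-concat of the normalized features followed by
        the head — the calibrated weights drop out entirely."""
        D, C = 5, 3
        net = CabifNet(D, C, seed=0, zero_init_last=True)
        fv, fa = rng.normal(size=(4, D)), rng.normal(size=(4, D))
        zv, za = rng.normal(size=(4, C)), rng.normal(size=(4, C))
        n = layer_normalize(fv, fa, net.fusion)
        expected = fuse_and_classify(
            ModulatedFeatures(fv_cm=n.fv_n, fa_cm=n.fa_n), net.fusion
        )
        got = net.predict(fv, fa, zv, za)
        np.testing.assert_allclose(got.z_fuse, expected.z_fuse, rtol=1e-12)
        # and the weights genuinely cannot matter: perturb the calibrator
        net.calib.tv[...] = 0.07
        net.calib.alpha[...] = 9.0
        np.testing.assert_allclose(
            net.predict(fv, fa, zv, za).z_fuse, expected.z_fuse, rtol=1e-12
        )

    def test_full_gradient_check(self, rng):
        """Analytic backprop for every parameter vs central differences."""
        D, C, B = 5, 4, 7
        net = CabifNet(D, C, H=3, seed=1)
        net.calib.tv[...] = 1.2
        net.calib.ta[...] = 0.9
        net.calib.alpha[...] = 1.8
        fv, fa = rng.normal(size=(B, D)), rng.normal(size=(B, D))
        zv, za = rng.normal(size=(B, C)), rng.normal(size=(B, C))
        y = rng.integers(0, C, size=B)

        def loss_of():
            cache = net.forward(fv, fa, zv, za)
            loss, dz = smoothed_cross_entropy(cache["out"].z_fuse, y, 0.02)
            return loss, cache, dz

        _, cache, dz = loss_of()
        grads = net.backward(cache, dz)
        eps = 1e-6
        for name, p in net.param_dict().items():
            flat = p.reshape(-1)
            probe = [0] if flat.size == 1 else [0, flat.size // 2, flat.size - 1]
            for j in probe:
                old = flat[j]
                flat[j] = old + eps
                lp, _, _ = loss_of()
                flat[j] = old - eps
                lm, _, _ = loss_of()
                flat[j] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = np.asarray(grads[name]).reshape(-1)[j]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9), name

    def test_crossed_variant_gradient_check(self, rng):
        D, C, B = 4, 3, 5
        net = CabifNet(D, C, H=2, variant="crossed", seed=6)
        fv, fa = rng.normal(size=(B, D)), rng.normal(size=(B, D))
        zv, za = rng.normal(size=(B, C)), rng.normal(size=(B, C))
        y = rng.integers(0, C, size=B)
        cache = net.forward(fv, fa, zv, za)
        loss, dz = smoothed_cross_entropy(cache["out"].z_fuse, y, 0.0)
        grads = net.backward(cache, dz)
        eps = 1e-6
        for name in ("W2_a2v", "Tv", "alpha", "g_f"):
            p = net.param_dict()[name].reshape(-1)
            old = p[0]
            p[0] = old + eps
            lp, _ = smoothed_cross_entropy(
                net.forward(fv, fa, zv, za)["out"].z_fuse, y, 0.0
            )
            p[0] = old - eps
            lm, _ = smoothed_cross_entropy(
                net.forward(fv, fa, zv, za)["out"].z_fuse, y, 0.0
            )
            p[0] = old
            numeric = (lp - lm) / (2 * eps)
            assert np.asarray(grads[name]).reshape(-1)[0] == pytest.approx(
                numeric, rel=1e-4, abs=1e-9
            )

    def test_one_training_step_touches_all_parameter_groups(self, rng):
        from cabif.pipeline import AdamW

        D, C, B = 6, 4, 16
        net = CabifNet(D, C, seed=2)
        params = net.param_dict()
        before = {k: v.copy() for k, v in params.items()}
        fv, fa = rng.normal(size=(B, D)), rng.normal(size=(B, D))
        zv, za = rng.normal(size=(B, C)) * 2, rng.normal(size=(B, C)) * 2
        y = rng.integers(0, C, size=B)
        cache = net.forward(fv, fa, zv, za)
        _, dz = smoothed_cross_entropy(cache["out"].z_fuse, y, 0.02)
        grads = net.backward(cache, dz)
        opt = AdamW({k: (1e-2 if k in net.CALIBRATOR_KEYS else 3e-4) for k in params},
                    weight_decay=1e-4, decay_keys=net.DECAY_KEYS)
        opt.step(params, grads)
        for name in ("W1_a2v", "W2_v2a", "W_head", "g_f", "Tv", "Ta", "alpha"):
            assert not np.array_equal(params[name], before[name]), name
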