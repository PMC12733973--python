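"""Saliency methods: closed forms, attribution axioms, fusion bounds, losses."""

import numpy as np
import pytest

from sonovis import nn
from sonovis.encoders import FeatureMap
from sonovis.explain import (GateNet, Heatmap, InterpreterHead, XaiConfig,
                             fixed_beta_fuse, gated_fuse, gradcam, gradcam_pp,
                             integrated_gradients, loss_xai,
                             mask_to_feature_grid, normalize_map,
                             total_variation)
from sonovis.nn import functional as F
from sonovis.nn.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestGradCAM:
    def test_linear_head_weights_proportional_to_w(self, rng):
        """y = sum_k w_k mean(A_k): alpha must be exactly w / (H*W)."""
        a = rng.normal(size=(4, 4, 3))
        w = np.array([0.5, -1.0, 2.0])
        grads = np.broadcast_to(w / 16.0, (4, 4, 3)).copy()
        from sonovis.explain import gradcam_weights
        alpha = gradcam_weights(grads)
        np.testing.assert_allclose(alpha, w / 16.0, atol=1e-12)

    def test_negative_weighted_sum_relu_annihilates(self, rng):
        a = np.abs(rng.normal(size=(4, 4, 2)))
        grads = -np.ones((4, 4, 2))          # alpha < 0 and A > 0
        heat = gradcam(a, grads)
        np.testing.assert_array_equal(heat.grid, 0.0)

    def test_alpha_matches_finite_difference_oracle(self, rng):
        """Random tiny CNN head: autodiff alphas vs central differences."""
        conv = nn.Conv2d(3, 4, 3, rng, padding=1)
        lin = nn.Linear(4, 1, rng)

        def head(a_arr):
            x = Tensor(a_arr, requires_grad=True)
            y = lin(conv(x.transpose((0, 3, 1, 2))).gelu()
                    .mean(axis=(2, 3)))[0, 0]
            return x, y

        a = rng.normal(size=(1, 5, 5, 3))
        x, y = head(a.copy())
        y.backward()
        alpha = x.grad[0].mean(axis=(0, 1))
        eps = 1e-4
        alpha_fd = np.zeros(3)
        for c in range(3):
            for i in range(5):
                for j in range(5):
                    up, dn = a.copy(), a.copy()
                    up[0, i, j, c] += eps
                    dn[0, i, j, c] -= eps
                    alpha_fd[c] += (head(up)[1].item() -
                                    head(dn)[1].item()) / (2 * eps)
        alpha_fd /= 25.0
        np.testing.assert_allclose(alpha, alpha_fd, atol=1e-3)

    def test_zero_gradients_warn_and_return_empty(self, rng, caplog):
        with caplog.at_level("WARNING", logger="sonovis.explain"):
            heat = gradcam(rng.normal(size=(4, 4, 2)), np.zeros((4, 4, 2)))
        assert "all-zero" in caplog.text
        np.testing.assert_array_equal(heat.grid, 0.0)


class TestGradCAMpp:
    def test_single_pixel_single_channel_equals_gradcam(self):
        a = np.array([[[2.0]]])
        g = np.array([[[0.7]]])
        np.testing.assert_array_equal(gradcam_pp(a, g).grid,
                                      gradcam(a, g).grid)

    def test_exp_surrogate_matches_symbolic_derivatives(self, rng):
        """For y = exp(<w, A>): d2y/dA2 = w^2 y and d3y/dA3 = w^3 y, so the
        channel ratio must equal sum(w^2) / (2 sum(w^2) + sum(A w^3))."""
        a = np.abs(rng.normal(size=(3, 3, 2))) + 0.5
        w = rng.normal(size=(3, 3, 2))
        heat = gradcam_pp(a, w, verbatim=True)
        num = (w ** 2).sum(axis=(0, 1))
        den = 2 * (w ** 2).sum(axis=(0, 1)) + (a * w ** 3).sum(axis=(0, 1))
        alpha = num / (den + 1e-8)
        cam = np.maximum((a * alpha).sum(-1), 0.0)
        expected = normalize_map(
            F.resize_matrix(64, 3) @ cam @ F.resize_matrix(64, 3).T)
        np.testing.assert_allclose(heat.grid, expected, atol=1e-5)

    def test_map_non_negative_for_any_input(self, rng):
        for _ in range(10):
            a = rng.normal(size=(4, 4, 3))
            g = rng.normal(size=(4, 4, 3))
            assert gradcam_pp(a, g).grid.min() >= 0.0


def linear_model_fn(w):
    def fn(s: Tensor) -> Tensor:
        return (s * Tensor(w.astype(s.dtype))).sum()
    return fn


class TestIntegratedGradients:
    def test_zero_path_gives_zero_attributions(self, rng):
        s = rng.uniform(size=(8, 12))
        _, attr, residual = integrated_gradients(
            linear_model_fn(rng.normal(size=(8, 12))), s, s.copy(), 0, 8)
        np.testing.assert_array_equal(attr, 0.0)
        assert residual < 1e-6

    @pytest.mark.parametrize("steps", [8, 64])
    def test_linear_model_exact_for_any_step_count(self, rng, steps):
        w = rng.normal(size=(6, 10))
        s = rng.uniform(size=(6, 10))
        _, attr, residual = integrated_gradients(linear_model_fn(w), s, None,
                                                 0, steps)
        np.testing.assert_allclose(attr, w * s, atol=1e-5)
        assert residual < 1e-4

    def test_completeness_residual_below_one_percent(self, rng):
        """Nonlinear model, 256 steps: attribution sum within 1% of the
        output difference (the completeness axiom)."""
        lin1 = nn.Linear(60, 16, rng, sd=0.3)
        lin2 = nn.Linear(16, 1, rng, sd=0.3)

        def fn(s: Tensor) -> Tensor:
            return lin2(lin1(s.reshape(1, 60)).gelu())[0, 0]

        s = rng.uniform(size=(6, 10)).astype(np.float32)
        _, attr, residual = integrated_gradients(fn, s, None, 0, 256)
        with nn.no_grad():
            delta = fn(Tensor(s)).item() - fn(Tensor(np.zeros_like(s))).item()
        assert residual < 0.01 * abs(delta)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(linear_model_fn(np.ones((4, 4))),
                                 np.ones((4, 4)), np.ones((4, 5)), 0, 8)


class TestInterpreterHead:
    @pytest.mark.parametrize("grid_w", [8, 4])
    def test_output_is_64_by_64(self, rng, grid_w):
        head = InterpreterHead(32, rng)
        fmap = FeatureMap(Tensor(rng.normal(
            size=(2, 8, grid_w, 32)).astype(np.float32)), "visual")
        out = head(fmap)
        assert out.shape == (2, 64, 64)

    def test_zero_weights_give_zero_map(self, rng):
        head = InterpreterHead(16, rng)
        for p in head.parameters():
            p.data[...] = 0.0
        fmap = FeatureMap(Tensor(rng.normal(
            size=(1, 8, 8, 16)).astype(np.float32)), "visual")
        np.testing.assert_array_equal(head(fmap).data, 0.0)

    def test_gradient_reaches_reduction_layer(self, rng):
        head = InterpreterHead(16, rng)
        fmap = FeatureMap(Tensor(rng.normal(
            size=(1, 8, 8, 16)).astype(np.float32)), "visual")
        (head(fmap) ** 2.0).sum().backward()
        assert head.reduce.weight.grad is not None
        assert np.abs(head.reduce.weight.grad).sum() > 0

    def test_wrong_grid_rejected(self, rng):
        head = InterpreterHead(16, rng)
        fmap = FeatureMap(Tensor(np.zeros((1, 6, 6, 16), np.float32)), "visual")
        with pytest.raises(ValueError):
            head(fmap)


class TestGatedFusion:
    def test_equal_maps_fixed_point(self, rng):
        g = normalize_map(rng.uniform(size=(64, 64)))
        hv = Heatmap(g, "visual", 0)
        ha = Heatmap(g.copy(), "acoustic", 0)
        fused, _ = gated_fuse(hv, ha, GateNet(rng))
        np.testing.assert_allclose(fused.grid, g, atol=1e-6)

    def test_saturated_gate_returns_visual_map(self, rng):
        gate = GateNet(rng)
        gate.conv2.weight.data[...] = 0.0
        gate.conv2.bias.data[...] = 50.0          # sigmoid -> 1
        hv = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "visual", 0)
        ha = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "acoustic", 0)
        fused, g = gated_fuse(hv, ha, gate)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)
        np.testing.assert_allclose(fused.grid, hv.grid, atol=1e-6)

    def test_pointwise_envelope_bound(self, rng):
        """min(Hv, Ha) <= Hc <= max(Hv, Ha) at every pixel, random maps."""
        gate = GateNet(rng)
        for _ in range(25):
            hv = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "visual", 0)
            ha = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "acoustic", 0)
            fused, _ = gated_fuse(hv, ha, gate)
            lo = np.minimum(hv.grid, ha.grid)
            hi = np.maximum(hv.grid, ha.grid)
            assert (fused.grid >= lo - 1e-7).all()
            assert (fused.grid <= hi + 1e-7).all()

    def test_weighted_region_integral_bound(self, rng):
        """Integral consequence of the pointwise envelope: for non-negative w,
        int(w min(Hv, Ha)) <= int(w Hc) <= int(w max(Hv, Ha)).  (A pixel-wise
        gate does not bound int(w Hc) by the per-modality integrals.)"""
        gate = GateNet(rng)
        for _ in range(10):
            hv = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "visual", 0)
            ha = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "acoustic", 0)
            fused, _ = gated_fuse(hv, ha, gate)
            w = rng.uniform(size=(64, 64))
            lo = (w * np.minimum(hv.grid, ha.grid)).sum()
            hi = (w * np.maximum(hv.grid, ha.grid)).sum()
            ic = (w * fused.grid).sum()
            assert lo - 1e-5 <= ic <= hi + 1e-5

    def test_fixed_beta_boundaries_and_arithmetic(self):
        lv = Heatmap(np.full((64, 64), 0.2), "visual", 0)
        la = Heatmap(np.full((64, 64), 0.6), "acoustic", 0)
        np.testing.assert_allclose(fixed_beta_fuse(lv, la, 1.0).grid, 0.2)
        np.testing.assert_allclose(fixed_beta_fuse(lv, la, 0.5).grid, 0.4)
        with pytest.raises(ValueError):
            fixed_beta_fuse(lv, la, 1.5)

    def test_gated_equals_fixed_beta_when_gate_is_constant(self, rng):
        beta = 0.73
        hv = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "visual", 0)
        ha = Heatmap(normalize_map(rng.uniform(size=(64, 64))), "acoustic", 0)
        manual = beta * hv.grid + (1 - beta) * ha.grid
        np.testing.assert_allclose(fixed_beta_fuse(hv, ha, beta).grid, manual)


class TestLossXai:
    def test_identical_maps_zero_alignment(self, rng):
        h = Tensor(rng.uniform(size=(64, 64)))
        total, parts = loss_xai(h, h.detach(), Tensor(np.ones((2, 2))),
                                np.ones((2, 2)), XaiConfig(mu_tv=0.0,
                                                           mu_gate=0.0))
        assert parts["align"] == pytest.approx(0.0, abs=1e-10)
        assert total.item() == pytest.approx(0.0, abs=1e-10)

    def test_constant_map_zero_tv(self):
        h = Tensor(np.full((64, 64), 0.4))
        assert total_variation(h).item() == 0.0
        assert total_variation(h, "isotropic").item() == pytest.approx(0.0,
                                                                       abs=1e-4)

    def test_full_mask_zero_gate_penalty(self, rng):
        f = Tensor(rng.normal(size=(8, 8, 4)))
        _, parts = loss_xai(Tensor(rng.uniform(size=(64, 64))),
                            Tensor(rng.uniform(size=(64, 64))), f,
                            np.ones((8, 8, 1)), XaiConfig())
        assert parts["gate"] == 0.0

    def test_kl_alignment_nonnegative_and_faithful(self, rng):
        """KL >= 0 always; zero only when the normalised maps coincide."""
        for _ in range(10):
            hc = Tensor(rng.uniform(size=(64, 64)))
            mc = Tensor(rng.uniform(size=(64, 64)))
            _, parts = loss_xai(hc, mc, Tensor(np.zeros((1, 1))),
                                np.ones((1, 1)), XaiConfig())
            assert parts["align"] >= 0.0
        shifted = hc + 3.21          # softmax shift-invariance: same map
        _, parts = loss_xai(hc, shifted, Tensor(np.zeros((1, 1))),
                            np.ones((1, 1)), XaiConfig())
        assert parts["align"] == pytest.approx(0.0, abs=1e-10)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            XaiConfig(mu_tv=-0.1)


def test_mask_downsampling_marks_foreground_blocks():
    mask = np.zeros((64, 64))
    mask[:32, :32] = 1.0
    down = mask_to_feature_grid(mask, (8, 8))
    assert down.shape == (8, 8)
    np.testing.assert_array_equal(down[:4, :4], 1.0)
    np.testing.assert_array_equal(down[4:, 4:], 0.0)
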