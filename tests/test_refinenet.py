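"""Refinement network: data assembly, architecture, loss, training mechanics."""

import numpy as np
import pytest

from vwiloc.core import (DisplacementField, GeometryError, ImageVolume,
                         VolumeGeometry)
from vwiloc.nn import autodiff as ad
from vwiloc.refinenet import (CropRescaleSpec, NetConfig, RefinementSample,
                              TrainingError, assemble_sample, build_network,
                              crop_and_rescale, masked_mse, predict_residual,
                              train_refiner, upscale_field)

TINY_GEOM = VolumeGeometry((8, 16, 16), (2.2, 2.2, 2.2))


def tiny_sample(seed=0, residual_scale=1.0, wiring="IM2dDVF"):
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(seed)
    target = ImageVolume(TINY_GEOM, rng.random(TINY_GEOM.dims))
    atlas = ImageVolume(TINY_GEOM, rng.random(TINY_GEOM.dims))
    stage1 = DisplacementField(TINY_GEOM, rng.normal(0, 1, TINY_GEOM.dims + (3,)))
    mask = ImageVolume(TINY_GEOM, np.ones(TINY_GEOM.dims))
    # smooth residual: what a registration error field actually looks like
    res = gaussian_filter(rng.normal(0, 1, TINY_GEOM.dims + (3,)), (2, 2, 2, 0))
    gt = DisplacementField(TINY_GEOM, stage1.vectors + residual_scale * res * 5)
    return assemble_sample(target, atlas, stage1, mask, gt, wiring)


class TestCropAndRescale:
    def test_acquisition_to_working_grid_dims(self):
        """A 240x384x318 acquisition maps to the 48x96x80 working grid."""
        geom = VolumeGeometry((240, 384, 318), (0.55,) * 3)
        img = ImageVolume(geom, np.zeros(geom.dims))
        out = crop_and_rescale(img, "image")
        assert out.geometry.dims == (48, 96, 80)
        np.testing.assert_allclose(out.geometry.spacing, (2.2, 2.2, 2.2))

    def test_constant_field_values_unchanged(self):
        geom = VolumeGeometry((96, 192, 160), (0.55,) * 3)
        vec = np.broadcast_to([1.0, -2.0, 0.5], geom.dims + (3,)).copy()
        spec = CropRescaleSpec((96, 192, 160), (24, 48, 40))
        out = crop_and_rescale(DisplacementField(geom, vec), "field", spec)
        np.testing.assert_allclose(
            out.vectors, np.broadcast_to([1.0, -2.0, 0.5], out.vectors.shape),
            atol=1e-12)

    def test_smooth_field_roundtrip(self):
        from vwiloc.phantom import sample_smooth_dvf
        geom = VolumeGeometry((96, 192, 160), (0.55,) * 3)
        spec = CropRescaleSpec((96, 192, 160), (24, 48, 40))
        fld = sample_smooth_dvf(5, geom, amplitude=3.0, knot_spacing=24.0)
        working = crop_and_rescale(fld, "field", spec)
        back = upscale_field(working, geom, spec)
        assert np.abs(back.vectors - fld.vectors).max() < 0.5

    def test_mask_stays_binary(self):
        geom = VolumeGeometry((96, 192, 160), (0.55,) * 3)
        rng = np.random.default_rng(1)
        mask = ImageVolume(geom, (rng.random(geom.dims) > 0.5).astype(float))
        spec = CropRescaleSpec((96, 192, 160), (24, 48, 40))
        out = crop_and_rescale(mask, "mask", spec)
        assert set(np.unique(out.values)) <= {0.0, 1.0}

    def test_oversized_crop_rejected(self):
        geom = VolumeGeometry((20, 96, 80), (1.0,) * 3)
        img = ImageVolume(geom, np.zeros(geom.dims))
        with pytest.raises(GeometryError):
            crop_and_rescale(img, "image", CropRescaleSpec((48, 96, 80), (24, 48, 40)))


class TestMaskedMse:
    def test_zero_for_equal_fields(self):
        f = np.random.default_rng(0).normal(size=(6, 6, 6, 3))
        assert masked_mse(f, f, np.ones((6, 6, 6))) == 0.0

    def test_constant_unit_residual(self):
        a = np.zeros((6, 6, 6, 3))
        b = np.zeros((6, 6, 6, 3))
        b[..., 0] = 1.0
        mask = np.zeros((6, 6, 6))
        mask[2:4] = 1
        assert masked_mse(a, b, mask) == pytest.approx(1.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 4, 4, 3))
        b = rng.normal(size=(4, 4, 4, 3))
        mask = rng.random((4, 4, 4)) > 0.4
        total, n = 0.0, 0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if mask[i, j, k]:
                        d = a[i, j, k] - b[i, j, k]
                        total += d @ d
                        n += 1
        assert masked_mse(a, b, mask) == pytest.approx(total / n, abs=1e-9)

    def test_empty_mask_rejected(self):
        f = np.zeros((4, 4, 4, 3))
        with pytest.raises(ValueError):
            masked_mse(f, f, np.zeros((4, 4, 4)))

    def test_loss_equals_squared_masked_rmse(self):
        """Consistency with the evaluation stack's RMSE discretization."""
        from vwiloc.metrics import dvf_rmse
        rng = np.random.default_rng(9)
        geom = VolumeGeometry((8, 8, 8))
        a = DisplacementField(geom, rng.normal(size=(8, 8, 8, 3)))
        b = DisplacementField(geom, rng.normal(size=(8, 8, 8, 3)))
        mask = rng.random((8, 8, 8)) > 0.3
        assert masked_mse(a.vectors, b.vectors, mask) == pytest.approx(
            dvf_rmse(a, b, mask) ** 2, abs=1e-9)


class TestAssembleSample:
    def test_channel_counts_per_wiring(self):
        s_dvf = tiny_sample(wiring="DVF2dDVF")
        s_im = tiny_sample(wiring="IM2dDVF")
        assert s_dvf.main_input.shape[0] == 4        # 3 DVF channels + mask
        assert s_dvf.attention_input.shape[0] == 2   # target VWI + difference
        assert s_im.main_input.shape[0] == 3         # target + atlas + mask
        assert s_im.attention_input.shape[0] == 4    # 3 DVF channels + difference

    def test_perfect_stage_one_zero_residual(self):
        s = tiny_sample(residual_scale=0.0)
        np.testing.assert_allclose(s.target_residual.vectors, 0.0, atol=1e-12)

    def test_identical_images_zero_difference_channel(self):
        rng = np.random.default_rng(4)
        img = ImageVolume(TINY_GEOM, rng.random(TINY_GEOM.dims))
        stage1 = DisplacementField.zero(TINY_GEOM)
        mask = ImageVolume(TINY_GEOM, np.ones(TINY_GEOM.dims))
        s = assemble_sample(img, img, stage1, mask, None, "IM2dDVF")
        np.testing.assert_allclose(s.attention_input[3], 0.0, atol=1e-6)

    def test_geometry_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        img = ImageVolume(TINY_GEOM, rng.random(TINY_GEOM.dims))
        other = VolumeGeometry((8, 16, 24), (2.2,) * 3)
        atlas = ImageVolume(other, rng.random(other.dims))
        with pytest.raises(GeometryError):
            assemble_sample(img, atlas, DisplacementField.zero(TINY_GEOM),
                            ImageVolume(TINY_GEOM, np.ones(TINY_GEOM.dims)),
                            None, "IM2dDVF")


class TestAttentionGate:
    def _gate(self):
        from vwiloc.refinenet import _AttentionGate
        rng = np.random.default_rng(0)
        return _AttentionGate(rng, 4, 4, 2, "g"), rng

    def test_large_positive_bias_passes_features_through(self):
        gate, rng = self._gate()
        gate.bpsi.v[:] = 50.0
        x = ad.Var(rng.random((4, 4, 4, 4)).astype(np.float32))
        h = ad.Var(rng.random((4, 4, 4, 4)).astype(np.float32))
        g = ad.Var(rng.random((2, 4, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(gate(x, h, g).v, x.v, atol=1e-4)

    def test_large_negative_bias_suppresses_features(self):
        gate, rng = self._gate()
        gate.bpsi.v[:] = -50.0
        x = ad.Var(rng.random((4, 4, 4, 4)).astype(np.float32))
        h = ad.Var(rng.random((4, 4, 4, 4)).astype(np.float32))
        g = ad.Var(rng.random((2, 4, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(gate(x, h, g).v, 0.0, atol=1e-4)

    def test_alpha_strictly_inside_unit_interval(self):
        gate, rng = self._gate()
        alphas = []
        for _ in range(20):
            x = ad.Var(rng.normal(size=(4, 5, 5, 5)).astype(np.float32))
            h = ad.Var(rng.normal(size=(4, 5, 5, 5)).astype(np.float32))
            g = ad.Var(rng.normal(size=(2, 5, 5, 5)).astype(np.float32))
            alphas.append(gate.alpha(x, h, g).v.ravel())
        a = np.concatenate(alphas)
        assert a.size >= 10_000 // 5
        assert np.all(a > 0.0) and np.all(a < 1.0)


class TestNetwork:
    def test_architecture_audit(self):
        net = build_network(NetConfig())
        d = net.describe()
        assert d["encoder_filters"] == [16, 32, 64, 128]
        assert d["conv_kernel"] == 3 and d["upconv_kernel"] == 2 and d["head_kernel"] == 1
        assert d["out_channels"] == 3
        assert d["n_attention_gates"] == 3          # one per skip connection
        assert d["n_residual_blocks"] == 7          # 4 encoder + 3 decoder
        assert d["residual_add_per_block"]
        assert d["hidden_activation"] == "relu" and d["head_activation"] is None
        assert d["head_zero_initialized"]

    def test_output_shape_matches_input(self):
        net = build_network(NetConfig(base_filters=2, main_channels=3,
                                      attention_channels=4))
        out = net.predict(np.zeros((3, 16, 16, 8), np.float32),
                          np.zeros((4, 16, 16, 8), np.float32))
        assert out.shape == (3, 16, 16, 8)

    def test_untrained_network_outputs_zero(self):
        rng = np.random.default_rng(0)
        net = build_network(NetConfig(base_filters=2, main_channels=3,
                                      attention_channels=4))
        out = net.predict(rng.random((3, 16, 16, 8)).astype(np.float32),
                          rng.random((4, 16, 16, 8)).astype(np.float32))
        assert np.all(out == 0.0)

    def test_indivisible_dims_rejected(self):
        net = build_network(NetConfig(base_filters=2, main_channels=1,
                                      attention_channels=1))
        with pytest.raises(GeometryError):
            net.predict(np.zeros((1, 10, 16, 16), np.float32),
                        np.zeros((1, 10, 16, 16), np.float32))


class TestTraining:
    CFG = NetConfig(levels=3, base_filters=2, main_channels=3, attention_channels=4)

    def test_untrained_corrected_equals_stage_one(self):
        s = tiny_sample()
        net = build_network(self.CFG)
        ddvf, corrected = predict_residual(net, s)
        np.testing.assert_allclose(ddvf.vectors, 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected.vectors, s.stage1_dvf.vectors)

    def test_zero_residual_dataset_keeps_zero_loss(self):
        s = tiny_sample(residual_scale=0.0)
        _, trace = train_refiner([s], self.CFG, epochs=2, seed=0)
        assert trace[0] < 1e-10

    def test_training_is_deterministic(self):
        s = tiny_sample()
        _, t1 = train_refiner([s], self.CFG, epochs=3, seed=5)
        _, t2 = train_refiner([s], self.CFG, epochs=3, seed=5)
        assert t1 == t2

    def test_loss_decreases_on_single_sample(self):
        s = tiny_sample(residual_scale=0.5)
        cfg = NetConfig(levels=3, base_filters=4, main_channels=3,
                        attention_channels=4)
        _, trace = train_refiner([s], cfg, epochs=150, seed=1, lr=3e-3)
        assert trace[-1] < 0.5 * trace[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrainingError):
            train_refiner([], self.CFG, epochs=1)

    def test_overfit_reduces_eval_rmse(self):
        from vwiloc.metrics import dvf_rmse
        s = tiny_sample(residual_scale=0.5, seed=8)
        net, _ = train_refiner([s], self.CFG, epochs=60, seed=2)
        _, corrected = predict_residual(net, s)
        gt = DisplacementField(s.stage1_dvf.geometry,
                               s.stage1_dvf.vectors + s.target_residual.vectors)
        assert dvf_rmse(corrected, gt, s.roi_mask) < dvf_rmse(s.stage1_dvf, gt, s.roi_mask)
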