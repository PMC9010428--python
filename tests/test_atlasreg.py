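"""Stage-one registration: MI, ranking, B-spline cascade, field composition."""

import numpy as np
import pytest

from vwiloc.atlasreg import (AffineTransform, BSplineTransform, DEFAULT_PARAMS,
                             RegistrationError, affine_footprint_mask,
                             bspline_register, compose_to_dvf,
                             mutual_information, rank_atlases, register_pair,
                             resample_with_dvf, rigid_register)
from vwiloc.core import DisplacementField, ImageVolume, VolumeGeometry
from vwiloc.warp import resample_image

from conftest import SMALL_GEOM

FAST = DEFAULT_PARAMS.fast()


class TestAffineTransform:
    def test_identity_maps_points_to_themselves(self):
        t = AffineTransform.identity()
        pts = np.random.default_rng(0).random((10, 3))
        np.testing.assert_allclose(t.apply(pts), pts)

    def test_matches_sitk_point_mapping(self):
        rng = np.random.default_rng(1)
        t = AffineTransform(np.eye(3) + 0.05 * rng.normal(size=(3, 3)),
                            rng.normal(size=3), rng.normal(size=3))
        st = t.to_sitk()
        pts = rng.random((20, 3)) * 10
        mine = t.apply(pts)
        theirs = np.array([st.TransformPoint(tuple(p)) for p in pts])
        np.testing.assert_allclose(mine, theirs, atol=1e-10)

    def test_singular_matrix_rejected(self):
        m = np.zeros((3, 3))
        with pytest.raises(RegistrationError):
            AffineTransform(m, np.zeros(3))

    def test_dict_roundtrip(self):
        t = AffineTransform(np.diag([1.0, 2.0, 0.5]), [1, 2, 3], [0.5, 0, 0])
        back = AffineTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(back.matrix, t.matrix)
        np.testing.assert_allclose(back.translation, t.translation)


class TestMutualInformation:
    GEOM = VolumeGeometry((24, 24, 24))

    def _noise(self, seed):
        return ImageVolume(self.GEOM,
                           np.random.default_rng(seed).random(self.GEOM.dims))

    def test_self_mi_is_maximal(self):
        a = self._noise(0)
        for seed in range(1, 5):
            assert mutual_information(a, a) >= mutual_information(a, self._noise(seed))

    def test_independent_noise_near_zero(self):
        geom = VolumeGeometry((48, 48, 48))
        vals = []
        for seed in range(4):
            a = ImageVolume(geom, np.random.default_rng(2 * seed).random(geom.dims))
            b = ImageVolume(geom, np.random.default_rng(2 * seed + 1).random(geom.dims))
            vals.append(mutual_information(a, b, bins=32))
        assert np.mean(vals) < 0.05

    def test_monotone_remap_preserves_mi(self):
        """An affine remap realigns bins exactly; a curved monotone remap
        loses only binning information."""
        a = self._noise(7)
        self_mi = mutual_information(a, a)
        affine = ImageVolume(self.GEOM, 2.0 * a.values + 5.0)
        assert mutual_information(a, affine) == pytest.approx(self_mi, abs=1e-9)
        curved = ImageVolume(self.GEOM, a.values + 0.3 * a.values**2)
        assert mutual_information(a, curved) > 0.8 * self_mi

    def test_nonnegative(self):
        for s in range(5):
            assert mutual_information(self._noise(s), self._noise(s + 10)) >= 0


class TestRigidRegister:
    def test_translation_recovered(self, small_template):
        vwi = small_template.vwi
        t = np.array([4.0, 0.0, 0.0])
        vec = np.broadcast_to(t, SMALL_GEOM.dims + (3,)).copy()
        shifted = resample_image(vwi, DisplacementField(SMALL_GEOM, vec), pad="nearest")
        tr = rigid_register(shifted, vwi, params=FAST)
        # pull-back transform maps target points by +t
        rec = tr.apply(np.zeros((1, 3)))[0]
        assert np.linalg.norm(rec - t) < 0.5 * min(SMALL_GEOM.spacing)

    def test_self_registration_near_identity(self, small_template):
        tr = rigid_register(small_template.vwi, small_template.vwi, params=FAST)
        assert np.abs(tr.matrix - np.eye(3)).max() < 1e-2
        rec = tr.apply(np.zeros((1, 3)))[0]
        assert np.linalg.norm(rec) < 0.3

    def test_constant_image_rejected(self, small_template):
        flat = ImageVolume(SMALL_GEOM, np.zeros(SMALL_GEOM.dims))
        with pytest.raises(RegistrationError):
            rigid_register(small_template.vwi, flat)


class TestRankAtlases:
    def test_self_copy_ranks_first(self, small_cohort):
        target = small_cohort[0].vwi
        atlases = [small_cohort[i].vwi for i in range(4)]
        ranking = rank_atlases(target, atlases, k=2, params=FAST)
        assert ranking.selected[0] == 0

    def test_k_clamped_to_library(self, small_cohort):
        target = small_cohort[0].vwi
        atlases = [small_cohort[i].vwi for i in range(3)]
        ranking = rank_atlases(target, atlases, k=10, params=FAST)
        assert len(ranking.selected) == 3

    def test_empty_library_rejected(self, small_cohort):
        with pytest.raises(RegistrationError):
            rank_atlases(small_cohort[0].vwi, [], k=1)


class TestBSpline:
    def test_knot_arithmetic_coefficients(self, small_template):
        """A 12-voxel knot grid on a 48-voxel axis carries 4+3 coefficients."""
        import SimpleITK as sitk
        from vwiloc.atlasreg import to_sitk
        geom = VolumeGeometry((48, 48, 48))
        img = sitk.Image(geom.dims, sitk.sitkFloat32)
        tx = sitk.BSplineTransformInitializer(img, [4, 4, 4], order=3)
        bt = BSplineTransform(tx, 12, 1)
        assert bt.coefficients.shape == (3, 7 * 7 * 7)

    def test_knot_spacing_floor_enforced(self):
        import SimpleITK as sitk
        img = sitk.Image((48, 48, 48), sitk.sitkFloat32)
        tx = sitk.BSplineTransformInitializer(img, [4, 4, 4], order=3)
        with pytest.raises(RegistrationError):
            BSplineTransform(tx, knot_spacing_vox=3)

    def test_self_registration_small_coefficients(self, small_template):
        bsps = bspline_register(small_template.vwi, small_template.vwi,
                                AffineTransform.identity(), params=FAST)
        coeff = np.concatenate([b.coefficients.ravel() for b in bsps])
        assert np.abs(coeff).max() < 0.5 * min(SMALL_GEOM.spacing)


class TestComposeToDvf:
    def test_identity_gives_zero_field(self):
        dvf = compose_to_dvf(AffineTransform.identity(), None, SMALL_GEOM)
        np.testing.assert_allclose(dvf.vectors, 0.0, atol=1e-9)

    def test_pure_translation_gives_constant_field(self):
        t = AffineTransform(np.eye(3), [2.0, -1.0, 0.5])
        dvf = compose_to_dvf(t, None, SMALL_GEOM)
        np.testing.assert_allclose(
            dvf.vectors, np.broadcast_to([2.0, -1.0, 0.5], dvf.vectors.shape),
            atol=1e-9)

    def test_point_mapping_matches_sequential_transforms(self, small_template):
        """d(p) = T_affine(T_bspline(p)) - p at random points."""
        import SimpleITK as sitk
        from vwiloc.atlasreg import to_sitk
        rng = np.random.default_rng(3)
        aff = AffineTransform(np.eye(3) + 0.02 * rng.normal(size=(3, 3)),
                              rng.normal(size=3))
        f = to_sitk(small_template.vwi)
        tx = sitk.BSplineTransformInitializer(f, [2, 3, 3], order=3)
        tx.SetParameters((rng.normal(0, 1.0, len(tx.GetParameters()))).tolist())
        bsp = BSplineTransform(tx, 12, 1)
        dvf = compose_to_dvf(aff, bsp, SMALL_GEOM)
        idx = rng.integers(0, np.asarray(SMALL_GEOM.dims) - 1, (100, 3))
        for i in idx:
            p = SMALL_GEOM.index_to_world(i)
            expect = aff.apply(np.array(tx.TransformPoint(tuple(p)))[None])[0]
            got = p + dvf.vectors[tuple(i)]
            np.testing.assert_allclose(got, expect, atol=1e-6)


class TestResampleWithDvf:
    def test_zero_field_identity_for_tree(self, small_template):
        dvf = DisplacementField.zero(SMALL_GEOM)
        out = resample_with_dvf(small_template.tree, dvf)
        np.testing.assert_allclose(out.all_points(),
                                   small_template.tree.all_points(), atol=1e-9)

    def test_unknown_type_rejected(self):
        with pytest.raises(TypeError):
            resample_with_dvf(42, DisplacementField.zero(SMALL_GEOM))


class TestFootprintMask:
    def test_identity_same_geometry_all_ones(self):
        mask = affine_footprint_mask(AffineTransform.identity(), SMALL_GEOM, SMALL_GEOM)
        assert np.all(mask.values == 1.0)

    def test_full_extent_translation_all_zeros(self):
        t = AffineTransform(np.eye(3), [1000.0, 0.0, 0.0])
        mask = affine_footprint_mask(t, SMALL_GEOM, SMALL_GEOM)
        assert np.all(mask.values == 0.0)

    def test_ten_voxel_translation_count(self):
        n1, n2, n3 = SMALL_GEOM.dims
        t = AffineTransform(np.eye(3), [10 * SMALL_GEOM.spacing[0], 0.0, 0.0])
        mask = affine_footprint_mask(t, SMALL_GEOM, SMALL_GEOM)
        assert int(mask.values.sum()) == (n1 - 10) * n2 * n3
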