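"""Synthetic cohort generator: determinism, contrasts, deformations."""

import numpy as np
import pytest

from vwiloc.core import DisplacementField, VolumeGeometry
from vwiloc.phantom import (CohortParams, PhantomParameterError,
                            centerline_contrast_fraction, make_cohort,
                            make_subject, make_template, make_vessel_tree,
                            render_pair, sample_smooth_dvf)
from vwiloc.warp import invert_points

from conftest import SMALL_GEOM, SMALL_PARAMS


class TestMakeVesselTree:
    EXTENT = (50.0, 50.0, 50.0)

    def test_single_branch_radii_in_range(self):
        tree = make_vessel_tree(1, 1, self.EXTENT)
        assert tree.n_branches == 1
        r = tree.all_radii()
        assert np.all(r >= 0.8) and np.all(r <= 2.5)

    def test_deterministic(self):
        a = make_vessel_tree(5, 3, self.EXTENT)
        b = make_vessel_tree(5, 3, self.EXTENT)
        np.testing.assert_array_equal(a.all_points(), b.all_points())

    def test_topology_single_root(self):
        tree = make_vessel_tree(2, 4, self.EXTENT)
        parents = [b.parent for b in tree.branches]
        assert tree.n_branches == 4
        assert parents.count(-1) == 1
        assert sum(p != -1 for p in parents) == 3

    def test_child_attaches_to_parent(self):
        tree = make_vessel_tree(3, 4, (60.0, 60.0, 60.0))
        for b in tree.branches:
            if b.parent < 0:
                continue
            parent = tree.branches[b.parent]
            d = np.linalg.norm(parent.points - b.points[0], axis=1).min()
            assert d <= 2.5          # within ~1 voxel of the parent centerline

    def test_tiny_extent_rejected(self):
        with pytest.raises(PhantomParameterError):
            make_vessel_tree(1, 1, (5.0, 5.0, 5.0))


class TestRenderPair:
    def test_noise_free_mra_background_exactly_zero(self, small_template):
        tree = small_template.tree
        _, mra = render_pair(tree, SMALL_GEOM, noise_sd=0.0, seed=0, bias=False)
        # voxels beyond the tube surface plus half a voxel diagonal are empty
        from scipy.spatial import cKDTree
        pts = tree.densified_points(0.5)
        radmax = tree.all_radii().max()
        centers = SMALL_GEOM.voxel_centers().reshape(-1, 3)
        d, _ = cKDTree(pts).query(centers)
        far = d > radmax + np.linalg.norm(SMALL_GEOM.spacing)
        assert np.all(mra.values.reshape(-1)[far] == 0.0)

    def test_mra_lumen_contrast_exceeds_noise(self, small_cohort):
        case = small_cohort[0]
        pts = case.tree.densified_points(1.0)
        inside = case.mra.sample(pts).mean()
        outside = np.median(case.mra.values)
        assert inside - outside >= 5 * SMALL_PARAMS.noise_sd

    def test_vwi_black_blood_contrast(self, small_cohort):
        case = small_cohort[0]
        pts = case.tree.densified_points(1.0)
        assert case.vwi.sample(pts).mean() < np.median(case.vwi.values)

    def test_reproducible(self):
        tree = make_vessel_tree(4, 2, (45.0, 95.0, 80.0))
        v1, m1 = render_pair(tree, SMALL_GEOM, seed=9)
        v2, m2 = render_pair(tree, SMALL_GEOM, seed=9)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_centerline_is_crosssection_extremum(self, small_template):
        assert centerline_contrast_fraction(small_template, "mra") >= 0.9
        assert centerline_contrast_fraction(small_template, "vwi") >= 0.9


class TestSampleSmoothDvf:
    def test_zero_amplitude_zero_field(self):
        dvf = sample_smooth_dvf(1, SMALL_GEOM, amplitude=0.0)
        assert np.all(dvf.vectors == 0)

    def test_amplitude_bounds_magnitude(self):
        dvf = sample_smooth_dvf(2, SMALL_GEOM, amplitude=3.0, knot_spacing=24.0)
        assert dvf.magnitude().max() == pytest.approx(3.0, rel=1e-9)

    def test_invertible_at_default_regime(self):
        dvf = sample_smooth_dvf(3, SMALL_GEOM, amplitude=3.0, knot_spacing=24.0)
        assert dvf.negative_jacobian_count() == 0

    def test_deterministic(self):
        a = sample_smooth_dvf(4, SMALL_GEOM)
        b = sample_smooth_dvf(4, SMALL_GEOM)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestMakeSubject:
    def test_identity_dvf_returns_template(self, small_template):
        case = make_subject(small_template, DisplacementField.zero(SMALL_GEOM))
        np.testing.assert_allclose(case.vwi.values, small_template.vwi.values, atol=1e-9)
        np.testing.assert_allclose(case.tree.all_points(),
                                   small_template.tree.all_points(), atol=1e-6)

    def test_pure_translation_shifts_tree_exactly(self, small_template):
        t = np.array([2.2, 0.0, 0.0])
        vec = np.broadcast_to(t, SMALL_GEOM.dims + (3,)).copy()
        case = make_subject(small_template, DisplacementField(SMALL_GEOM, vec))
        np.testing.assert_allclose(case.tree.all_points(),
                                   small_template.tree.all_points() - t, atol=1e-6)

    def test_tree_roundtrip_through_field(self, small_template):
        dvf = sample_smooth_dvf(11, SMALL_GEOM, amplitude=3.0)
        case = make_subject(small_template, dvf)
        # map warped points forward through the field: should recover originals
        back = case.tree.all_points() + dvf.sample(case.tree.all_points())
        err = np.linalg.norm(back - small_template.tree.all_points(), axis=1)
        assert np.percentile(err, 99) < 0.5 * min(SMALL_GEOM.spacing)

    def test_intensity_roundtrip(self, small_template):
        """Warping there and back recovers the template to a few percent."""
        from vwiloc.warp import resample_image
        dvf = sample_smooth_dvf(13, SMALL_GEOM, amplitude=3.0, knot_spacing=24.0)
        warped = resample_image(small_template.vwi, dvf, pad="nearest")
        # numerically invert the field on the grid
        centers = SMALL_GEOM.voxel_centers().reshape(-1, 3)
        inv_pts = invert_points(dvf, centers)
        inv = DisplacementField(SMALL_GEOM, (inv_pts - centers).reshape(SMALL_GEOM.dims + (3,)))
        back = resample_image(warped, inv, pad="nearest")
        core = (slice(2, -2),) * 3
        err = back.values[core] - small_template.vwi.values[core]
        nrms = np.sqrt((err**2).mean()) / np.ptp(small_template.vwi.values)
        assert nrms < 0.05


class TestMakeCohort:
    def test_shapes_and_sharing(self, small_cohort):
        assert len(small_cohort) == 5
        assert all(c.geometry == SMALL_GEOM for c in small_cohort)
        assert all(len(c.segments) == 4 for c in small_cohort)

    def test_noise_independence(self, small_cohort):
        a, b = small_cohort[0], small_cohort[1]
        assert not np.array_equal(a.vwi.values, b.vwi.values)

    def test_subjects_differ_in_deformation(self, small_cohort):
        for i in range(len(small_cohort)):
            for j in range(i + 1, len(small_cohort)):
                di = small_cohort[i].true_dvf_from_template.vectors
                dj = small_cohort[j].true_dvf_from_template.vectors
                assert np.abs(di - dj).mean() > 0

    def test_deterministic(self):
        a = make_cohort(2, 3, SMALL_PARAMS)
        b = make_cohort(2, 3, SMALL_PARAMS)
        np.testing.assert_array_equal(a[0].vwi.values, b[0].vwi.values)
        np.testing.assert_array_equal(a[1].mra.values, b[1].mra.values)

    def test_otsu_cannot_isolate_lumen(self, small_cohort):
        """Two-class thresholding fails on VWI: the lumen is a tiny minority
        of whichever class it falls into."""
        from skimage.filters import threshold_otsu
        case = small_cohort[0]
        thr = threshold_otsu(case.vwi.values)
        lumen_pts = case.tree.densified_points(1.0)
        lumen_vals = case.vwi.sample(lumen_pts)
        dark_class = case.vwi.values < thr
        lumen_in_dark = np.mean(lumen_vals < thr)
        frac_of_class = (lumen_in_dark * len(lumen_vals)) / max(dark_class.sum(), 1)
        assert frac_of_class < 0.5

    def test_too_few_subjects_rejected(self):
        with pytest.raises(PhantomParameterError):
            make_cohort(1, 0, SMALL_PARAMS)
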