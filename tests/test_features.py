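"""Texture and first-order feature extraction against hand calculations
and independent brute-force references."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import ball_mask, make_roi
from oracles import glcm_brute, glrlm_brute, glzlm_brute, ngldm_brute
from radsurv.errors import EmptyRoiError
from radsurv.features import (DIRECTIONS_13, NGLDM_EPSILON, discretize_roi,
                              extract_all, extract_roi_features,
                              first_order_features, glcm_features, glcm_matrix,
                              glrlm_features, glrlm_matrix, glzlm_features,
                              glzlm_matrix, ngldm_features, ngldm_table)
from radsurv.io import ImageVolume, RoiMask


def random_droi(seed, shape=(4, 4, 4), n_levels=8):
    rng = np.random.default_rng(seed)
    vol, mask = make_roi(rng.normal(0, 1, shape), mask=rng.random(shape) < 0.8)
    if not mask.voxels.any():
        mask = RoiMask(np.ones(shape))
    return discretize_roi(vol, mask, n_levels)


class TestDiscretization:
    def test_three_point_example(self):
        vol, mask = make_roi([[[0.0, 50.0, 100.0]]])
        assert discretize_roi(vol, mask, 64).in_roi_levels().tolist() == [1, 33, 64]

    def test_uniform_roi_maps_to_level_one(self):
        vol, mask = make_roi(np.full((3, 3, 3), 7.0))
        assert set(discretize_roi(vol, mask, 64).in_roi_levels()) == {1}

    def test_empty_mask_rejected(self):
        vol, mask = make_roi(np.zeros((3, 3, 3)), mask=np.zeros((3, 3, 3)))
        with pytest.raises(EmptyRoiError):
            discretize_roi(vol, mask, 64)

    @given(st.integers(0, 10**6))
    def test_bounds_and_extremes(self, seed):
        """In-ROI levels live in [1, N]; the min maps to 1, the max to N."""
        rng = np.random.default_rng(seed)
        vol, mask = make_roi(rng.normal(0, 10, (3, 4, 5)), mask=rng.random((3, 4, 5)) < 0.7)
        if not mask.voxels.any():
            return
        droi = discretize_roi(vol, mask, 64)
        levels = droi.in_roi_levels()
        assert levels.min() >= 1 and levels.max() <= 64
        vals = vol.intensities[mask.voxels]
        lv = droi.levels[mask.voxels]
        assert lv[np.argmin(vals)] == 1
        if vals.max() > vals.min():
            assert lv[np.argmax(vals)] == 64

    def test_affine_transform_leaves_discretized_features_unchanged(self):
        """Relative min-max resampling removes intensity scale and offset:
        every feature except the raw-intensity statistics is invariant
        under a strictly increasing affine transform."""
        rng = np.random.default_rng(3)
        arr = rng.normal(100, 15, (5, 6, 6))
        mask = rng.random((5, 6, 6)) < 0.8
        vol1, m = make_roi(arr, mask=mask)
        vol2, _ = make_roi(3.1 * arr + 42.0, mask=mask)
        f1 = extract_roi_features(vol1, m)
        f2 = extract_roi_features(vol2, m)
        raw_scale = {"firstorder_min", "firstorder_max", "firstorder_mean", "firstorder_std"}
        for name in f1:
            if name not in raw_scale:
                assert f1[name] == pytest.approx(f2[name], abs=1e-12), name


class TestFirstOrder:
    def test_uniform_roi(self):
        vol, mask = make_roi(np.full((3, 3, 3), 5.0))
        f = first_order_features(vol, mask)
        assert f["std"] == 0.0
        assert f["entropy"] == pytest.approx(0.0)
        assert f["uniformity"] == 1.0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_volume_of_unit_cube(self):
        """8 voxels at 1 mm spacing: 8 voxels and 0.008 ml."""
        arr = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        vol, m = make_roi(arr, mask=mask)
        f = first_order_features(vol, m)
        assert f["volume_voxels"] == 8
        assert f["volume_ml"] == pytest.approx(0.008)

    def test_ball_more_spherical_than_slab(self):
        shape = (13, 13, 13)
        ball = ball_mask(shape, (6, 6, 6), 5.2)
        v = int(ball.sum())
        slab = np.ones((1, 1, v), dtype=bool)  # equal-volume 1x1xV rod
        vol_b, m_b = make_roi(np.zeros(shape), mask=ball)
        vol_s, m_s = make_roi(np.zeros((1, 1, v)), mask=slab)
        s_ball = first_order_features(vol_b, m_b)["sphericity"]
        s_slab = first_order_features(vol_s, m_s)["sphericity"]
        assert m_b.n_voxels == m_s.n_voxels == v
        assert s_ball > s_slab

    def test_single_voxel_moments_missing(self):
        vol, mask = make_roi(np.zeros((1, 1, 1)))
        f = first_order_features(vol, mask)
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])


class TestGlcm:
    def test_uniform_roi_single_cell(self):
        droi = discretize_roi(*make_roi(np.full((3, 3, 3), 2.0)), 64)
        f = glcm_features(droi)
        assert f["homogeneity"] == 1.0
        assert f["energy"] == 1.0
        assert f["contrast"] == 0.0
        assert f["dissimilarity"] == 0.0
        assert f["entropy"] == pytest.approx(0.0)
        assert np.isnan(f["correlation"])

    def test_2x2x1_matches_exhaustive_enumeration(self):
        vol, mask = make_roi([[[0.0, 0.0], [100.0, 100.0]]])
        droi = discretize_roi(vol, mask, 2)
        assert droi.levels.tolist() == [[[1, 1], [2, 2]]]
        mine = glcm_matrix(droi)
        brute = glcm_brute(droi.levels, 2, DIRECTIONS_13)
        np.testing.assert_array_equal(mine, brute)
        # features from the hand-normalized matrix
        p = brute / brute.sum()
        f = glcm_features(droi)
        assert f["energy"] == pytest.approx((p**2).sum())
        assert f["contrast"] == pytest.approx(
            sum((i - j) ** 2 * p[i - 1, j - 1] for i in (1, 2) for j in (1, 2)))

    def test_grey_level_inversion_symmetry(self):
        from radsurv.features import DiscretizedRoi

        droi = random_droi(7)
        inv_levels = np.where(droi.levels > 0, droi.n_levels + 1 - droi.levels, 0)
        inverted = DiscretizedRoi(inv_levels, droi.n_levels, 0.0, 1.0)
        f, g = glcm_features(droi), glcm_features(inverted)
        for name in ("contrast", "homogeneity", "energy", "entropy", "dissimilarity"):
            assert f[name] == pytest.approx(g[name], abs=1e-12), name

    def test_probabilities_sum_to_one(self):
        droi = random_droi(11)
        counts = glcm_matrix(droi)
        assert (counts / counts.sum()).sum() == pytest.approx(1.0)


class TestGlrlm:
    def test_single_run_single_direction(self):
        vol, mask = make_roi(np.ones((1, 1, 5)))
        droi = discretize_roi(vol, mask, 64)
        f = glrlm_features(droi, directions=[(0, 0, 1)])
        assert f["sre"] == pytest.approx(1 / 25)
        assert f["lre"] == pytest.approx(25)
        assert f["rp"] == pytest.approx(1 / 5)

    def test_uniform_line_runs(self):
        vol, mask = make_roi(np.ones((1, 1, 6)))
        droi = discretize_roi(vol, mask, 64)
        mat = glrlm_matrix(droi, directions=[(0, 0, 1)])
        assert mat[0, 5] == 1 and mat.sum() == 1

    def test_maximal_fragmentation(self):
        """All-distinct levels: every run has length 1, so SRE = RP = 1."""
        vol, mask = make_roi(np.arange(27.0).reshape(3, 3, 3))
        droi = discretize_roi(vol, mask, 27)
        f = glrlm_features(droi)
        assert f["sre"] == 1.0
        assert f["rp"] == 1.0

    def test_pooled_matrix_matches_line_walker(self):
        for seed in range(5):
            droi = random_droi(seed)
            np.testing.assert_array_equal(
                glrlm_matrix(droi), glrlm_brute(droi.levels, droi.n_levels, DIRECTIONS_13))


class TestNgldm:
    def test_uniform_roi_coarseness_guard(self):
        droi = discretize_roi(*make_roi(np.full((3, 3, 3), 1.0)), 64)
        f = ngldm_features(droi)
        assert f["coarseness"] == pytest.approx(1.0 / NGLDM_EPSILON)
        assert np.isnan(f["busyness"]) and np.isnan(f["contrast"])

    def test_center_voxel_hand_enumeration(self):
        arr = np.ones((3, 3, 3))
        arr[1, 1, 1] = 2.0
        vol, mask = make_roi(arr * 100)
        droi = discretize_roi(vol, mask, 2)
        counts, sums = ngldm_table(droi)
        bc, bs = ngldm_brute(droi.levels, 2)
        np.testing.assert_array_equal(counts, bc)
        np.testing.assert_allclose(sums, bs, atol=1e-12)
        # center: 26 neighbours of level 1 -> |2 - 1| = 1
        assert sums[1] == pytest.approx(1.0)

    def test_contrast_scales_with_cubed_level_distance(self):
        """For a two-level pattern, both (i-j)^2 and the difference sums
        scale with the level distance, so contrast scales with its cube."""
        base = np.zeros((3, 3, 4))
        base[:, :, :2] = 1.0
        f1 = ngldm_features(discretize_roi(*make_roi(base), 2))
        f2 = ngldm_features(discretize_roi(*make_roi(base), 3))
        # N=2 gives levels {1,2}; N=3 gives {1,3}: distance doubles
        assert f2["contrast"] / f1["contrast"] == pytest.approx(8.0)


class TestGlzlm:
    def test_uniform_roi_single_zone(self):
        vol, mask = make_roi(np.full((4, 4, 4), 3.0))
        f = glzlm_features(discretize_roi(vol, mask, 64))
        v = 64
        assert f["zp"] == pytest.approx(1 / v)
        assert f["sze"] == pytest.approx(1 / v**2)
        assert f["lze"] == pytest.approx(float(v**2))

    def test_two_disjoint_blobs_two_zones(self):
        arr = np.zeros((3, 3, 7))
        arr[:, :, :2] = 50.0
        arr[:, :, 5:] = 50.0
        vol, mask = make_roi(arr, mask=arr > 0)
        mat = glzlm_matrix(discretize_roi(vol, mask, 64))
        assert mat.sum() == 2

    def test_maximal_fragmentation(self):
        vol, mask = make_roi(np.arange(27.0).reshape(3, 3, 3))
        f = glzlm_features(discretize_roi(vol, mask, 27))
        assert f["zp"] == 1.0

    def test_zones_match_flood_fill(self):
        for seed in range(5):
            droi = random_droi(seed + 50)
            np.testing.assert_array_equal(
                glzlm_matrix(droi), glzlm_brute(droi.levels, droi.n_levels))


class TestAssembly:
    def test_feature_counts_and_family_partition(self):
        rng = np.random.default_rng(0)
        vol1 = ImageVolume(rng.normal(100, 10, (6, 8, 8)), (5, 1, 1), "T1CE")
        vol2 = ImageVolume(rng.normal(80, 12, (6, 8, 8)), (5, 1, 1), "T2")
        mask_t = RoiMask(ball_mask((6, 8, 8), (3, 3, 3), 2.5), "tumor")
        mask_n = RoiMask(ball_mask((6, 8, 8), (3, 6, 6), 1.5), "node")
        out = extract_all({"T1CE": vol1, "T2": vol2}, {"tumor": mask_t, "node": mask_n})
        for structure in ("tumor", "node"):
            assert len(out[structure]) == 86
            for seq in ("T1CE", "T2"):
                per_seq = [k for k in out[structure] if k.startswith(f"{seq}_")]
                assert len(per_seq) == 43
                by_family = {
                    fam: sum(k.startswith(f"{seq}_{fam}_") for k in per_seq)
                    for fam in ("firstorder", "glcm", "glrlm", "ngldm", "glzlm")
                }
                assert by_family == {"firstorder": 12, "glcm": 6, "glrlm": 11,
                                     "ngldm": 3, "glzlm": 11}

    def test_axis_permutation_invariance(self):
        """Permuting array axes (with spacing permuted too) leaves all 43
        features unchanged: the direction sets are symmetric."""
        rng = np.random.default_rng(5)
        arr = rng.normal(0, 1, (4, 5, 6))
        mask = rng.random((4, 5, 6)) < 0.7
        vol, m = make_roi(arr, spacing=(5.0, 1.0, 2.0), mask=mask)
        perm = (2, 0, 1)
        vol_p = ImageVolume(np.transpose(arr, perm), tuple(np.array((5.0, 1.0, 2.0))[list(perm)]))
        m_p = RoiMask(np.transpose(mask, perm))
        f1 = extract_roi_features(vol, m)
        f2 = extract_roi_features(vol_p, m_p)
        for name in f1:
            np.testing.assert_allclose(f1[name], f2[name], atol=1e-10, err_msg=name)

    def test_empty_mask_raises(self):
        vol, _ = make_roi(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyRoiError):
            extract_roi_features(vol, RoiMask(np.zeros((3, 3, 3))))

    def test_run_and_zone_percentages_bounded(self):
        for seed in (1, 2, 3):
            droi = random_droi(seed + 100, shape=(5, 5, 5))
            assert 0 < glrlm_features(droi)["rp"] <= 1
            assert 0 < glzlm_features(droi)["zp"] <= 1
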