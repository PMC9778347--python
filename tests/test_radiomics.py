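"""Radiomics features: analytic geometry values, hand-computed statistics,
exhaustive texture oracles and the correlation-based selection."""

import numpy as np
import pytest

from fetalbrain.radiomics import (
    SELECTED_FEATURE_NAMES, _discretize, extract_features, firstorder_features,
    glcm_features, _glcm_offsets, ngtdm_features, select_features,
    shape_features,
)


def ball(radius, extent=None, spacing=1.0):
    extent = extent or int(2 * radius + 5)
    c = (extent - 1) / 2
    g = np.mgrid[:extent, :extent, :extent]
    return ((g[0] - c) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2) <= (radius / spacing) ** 2


def ellipsoid(semi, extent=32):
    c = (extent - 1) / 2
    g = np.mgrid[:extent, :extent, :extent]
    return sum(((g[i] - c) / semi[i]) ** 2 for i in range(3)) <= 1.0


# --------------------------------------------------------- texture oracles
def brute_glcm_features(image, mask, n_levels):
    """Exhaustive voxel-pair enumeration over the 13 offsets."""
    levels = np.zeros(mask.shape, dtype=int)
    levels[mask] = _discretize(image[mask].astype(float), n_levels)
    acc = np.zeros((n_levels, n_levels))
    n_used = 0
    for off in _glcm_offsets():
        p = np.zeros((n_levels, n_levels))
        cnt = 0
        for idx in np.ndindex(mask.shape):
            j = tuple(np.add(idx, off))
            if any(a < 0 or a >= s for a, s in zip(j, mask.shape)):
                continue
            if mask[idx] and mask[j]:
                p[levels[idx] - 1, levels[j] - 1] += 1
                p[levels[j] - 1, levels[idx] - 1] += 1
                cnt += 1
        if cnt:
            acc += p / p.sum()
            n_used += 1
    p = acc / n_used
    i = np.arange(1, n_levels + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu = (p * ii).sum()
    var = (p * (ii - mu) ** 2).sum()
    corr = None if var < 1e-24 else ((p * (ii - mu) * (jj - mu)).sum()) / var
    return {
        "contrast": (p * (ii - jj) ** 2).sum(),
        "correlation": corr,
        "inverse_diff_moment": (p / (1 + (ii - jj) ** 2)).sum(),
    }


def brute_ngtdm(image, mask, n_levels):
    """Per-voxel 26-neighbourhood averages by direct looping."""
    levels = np.zeros(mask.shape, dtype=int)
    levels[mask] = _discretize(image[mask].astype(float), n_levels)
    p = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        neigh = []
        for off in np.ndindex(3, 3, 3):
            if off == (1, 1, 1):
                continue
            j = tuple(np.add(idx, off) - 1)
            if any(a < 0 or a >= n for a, n in zip(j, mask.shape)):
                continue
            if mask[j]:
                neigh.append(levels[j])
        if not neigh:
            continue
        lev = levels[idx]
        p[lev - 1] += 1
        s[lev - 1] += abs(lev - np.mean(neigh))
    n_vp = p.sum()
    return p / n_vp, s, int(n_vp)


class TestShapeFeatures:
    def test_digital_ball_sphericity_and_diameter(self):
        feats = shape_features(ball(10.0), spacing=(1, 1, 1))
        assert feats["sphericity"] == pytest.approx(1.0, abs=0.05)
        assert feats["max_3d_diameter"] == pytest.approx(20.0, rel=0.05)
        assert feats["elongation"] == pytest.approx(1.0, abs=0.05)

    def test_ellipsoid_axis_ratios(self):
        feats = shape_features(ellipsoid((12, 6, 6), extent=30))
        assert feats["elongation"] == pytest.approx(0.5, rel=0.10)
        assert feats["flatness"] == pytest.approx(0.5, rel=0.10)
        assert feats["major_axis_length"] > feats["minor_axis_length"]

    def test_flat_slab_limit(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 8] = True
        feats = shape_features(mask)
        assert feats["flatness"] < 0.1
        assert feats["elongation"] == pytest.approx(1.0, abs=0.05)

    def test_surface_area_of_unit_cube_voxel_block(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[3:7, 3:7, 3:7] = True  # 4x4x4 block: true area 96
        feats = shape_features(mask)
        # marching cubes bevels corners; allow a generous band around 96
        assert 60 < feats["surface_area"] < 110

    def test_translation_invariance(self, rng):
        mask = np.zeros((20, 20, 20), bool)
        mask[4:9, 5:11, 6:10] = True
        base = shape_features(mask)
        shifted = np.roll(mask, (3, 2, 4), axis=(0, 1, 2))
        moved = shape_features(shifted)
        for key in base:
            assert moved[key] == pytest.approx(base[key], rel=1e-4)

    def test_spacing_covariance(self):
        mask = ellipsoid((6, 5, 4), extent=18)
        f1 = shape_features(mask, spacing=(1, 1, 1))
        f2 = shape_features(mask, spacing=(2, 2, 2))
        assert f2["major_axis_length"] == pytest.approx(2 * f1["major_axis_length"], rel=1e-6)
        assert f2["max_3d_diameter"] == pytest.approx(2 * f1["max_3d_diameter"], rel=1e-6)
        assert f2["surface_area"] == pytest.approx(4 * f1["surface_area"], rel=1e-6)
        for key in ("elongation", "flatness", "sphericity"):
            assert f2[key] == pytest.approx(f1[key], rel=1e-6)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="degenerate|empty"):
            shape_features(mask)


class TestFirstOrder:
    def test_constant_image_entropy_zero_and_flags(self):
        mask = np.ones((4, 4, 4), bool)
        feats = firstorder_features(np.full((4, 4, 4), 3.0), mask)
        assert feats["entropy"] == 0.0
        assert feats["skewness"] is None and feats["kurtosis"] is None

    def test_uniform_fill_of_16_bins_gives_4_bits(self):
        vals = np.repeat(np.arange(16, dtype=float), 4)
        img = vals.reshape(4, 4, 4)
        feats = firstorder_features(img, np.ones((4, 4, 4), bool), n_bins=16)
        assert feats["entropy"] == pytest.approx(4.0)

    def test_hand_computed_toy_list(self):
        img = np.array([1.0, 2.0, 2.0, 3.0]).reshape(1, 1, 4)
        feats = firstorder_features(img, np.ones((1, 1, 4), bool))
        assert feats["mean"] == pytest.approx(2.0)
        assert feats["energy"] == pytest.approx(18.0)
        assert feats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_sample_moments(self, rng):
        img = rng.normal(5.0, 2.0, size=(12, 12, 12))
        feats = firstorder_features(img, np.ones(img.shape, bool))
        assert feats["mean"] == pytest.approx(5.0, abs=0.2)
        assert feats["kurtosis"] == pytest.approx(3.0, abs=0.3)  # non-excess


class TestGlcm:
    def test_constant_region_contrast_zero_idm_one(self):
        img = np.full((4, 4, 4), 2.0)
        feats = glcm_features(img, np.ones((4, 4, 4), bool), n_levels=8)
        assert feats["contrast"] == 0.0
        assert feats["inverse_diff_moment"] == pytest.approx(1.0)
        assert feats["correlation"] is None

    def test_checkerboard_single_offset_matches_pair_counting(self):
        img = np.indices((4, 4, 4)).sum(axis=0) % 2.0
        mask = np.ones((4, 4, 4), bool)
        offset = np.array([[0, 0, 1]])
        feats = glcm_features(img, mask, n_levels=2, offsets=offset)
        # along z every adjacent pair is unlike: all mass off-diagonal
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["inverse_diff_moment"] == pytest.approx(0.5)

    def test_random_region_equals_exhaustive_oracle(self, rng):
        img = rng.uniform(size=(5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) > 0.3
        ours = glcm_features(img, mask, n_levels=4)
        oracle = brute_glcm_features(img, mask, 4)
        for key in ours:
            assert ours[key] == pytest.approx(oracle[key], abs=1e-9)


class TestNgtdm:
    def test_constant_region_guard_capped_coarseness(self):
        img = np.full((4, 4, 4), 1.0)
        feats = ngtdm_features(img, np.ones((4, 4, 4), bool), n_levels=8)
        assert feats["coarseness"] == pytest.approx(1e6)
        assert feats["complexity"] == 0.0

    def test_striped_region_matches_neighbourhood_oracle(self):
        img = np.zeros((4, 4, 4))
        img[::2] = 1.0
        mask = np.ones((4, 4, 4), bool)
        p_o, s_o, n_o = brute_ngtdm(img, mask, 2)
        from fetalbrain.radiomics import ngtdm_table

        p, s, n = ngtdm_table(img, mask, 2)
        np.testing.assert_allclose(p, p_o, atol=1e-12)
        np.testing.assert_allclose(s, s_o, atol=1e-9)
        assert n == n_o

    def test_random_region_equals_oracle(self, rng):
        img = rng.uniform(size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.25
        from fetalbrain.radiomics import ngtdm_table

        p, s, n = ngtdm_table(img, mask, 3)
        p_o, s_o, n_o = brute_ngtdm(img, mask, 3)
        np.testing.assert_allclose(p, p_o, atol=1e-12)
        np.testing.assert_allclose(s, s_o, atol=1e-9)
        assert n == n_o


class TestFullVectorAndSelection:
    def test_extractor_yields_all_18_canonical_names(self, phantom48):
        img, lab, _ = phantom48
        feats = extract_features(img.voxels, lab.labels > 0, spacing=img.spacing)
        assert tuple(feats) == SELECTED_FEATURE_NAMES
        assert all(np.isfinite(v) for v in feats.values())

    def test_duplicated_column_kept_once(self, rng):
        x = rng.normal(size=(30, 3))
        x[:, 2] = x[:, 0]  # exact duplicate
        y = x[:, 0] * 2 + rng.normal(size=30) * 0.1
        kept = select_features(x, y, ["a", "b", "a_copy"], r_thresh=0.95)
        assert ("a" in kept) ^ ("a_copy" in kept)

    def test_target_copy_ranked_first(self, rng):
        x = rng.normal(size=(25, 4))
        y = x[:, 2].copy()
        kept = select_features(x, y, list("abcd"))
        assert kept[0] == "c"

    def test_constant_column_skipped_with_warning(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        y = x[:, 0]
        with pytest.warns(UserWarning, match="constant"):
            kept = select_features(x, y, list("abc"))
        assert "b" not in kept
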