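"""Discretization, first-order features and the texture-feature families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomrad.features import (ExtractionSettings, FEATURE_NAMES,
                                 FAMILY_SIZES, DiscretizedRoi, discretize,
                                 extract_feature_vector, first_order_features,
                                 glcm_features, gldm_features, glrlm_features,
                                 glszm_features, ngtdm_features)
from phantomrad.features.firstorder import FIRSTORDER_NAMES
from phantomrad.volume import VolumeImage


class TestDiscretize:
    def test_floor_rule(self):
        assert list(discretize([0, 24.9, 25, 50], 25)) == [1, 1, 2, 3]

    def test_constant_input_is_single_bin(self):
        levels = discretize([5.0] * 10, 25)
        assert set(levels) == {1}

    @given(st.lists(st.floats(-2000, 3000, allow_nan=False), min_size=1,
                    max_size=50),
           st.floats(0.5, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_minimum_maps_to_level_one(self, values, bw):
        levels = discretize(values, bw)
        assert levels[int(np.argmin(values))] == 1
        assert levels.min() == 1

    @given(st.lists(st.floats(-500, 500, allow_nan=False), min_size=2,
                    max_size=30),
           st.floats(-300, 300))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, values, c):
        a = discretize(np.asarray(values), 25)
        b = discretize(np.asarray(values) + c, 25)
        assert np.array_equal(a, b)

    def test_empty_and_bad_binwidth_rejected(self):
        with pytest.raises(ValueError):
            discretize([], 25)
        with pytest.raises(ValueError):
            discretize([1.0], 0.0)


class TestFirstOrder:
    def test_constant_roi_degenerate_values(self):
        feats, deg = first_order_features([7.0] * 20, voxel_volume=2.0)
        assert feats["Mean"] == 7.0
        assert feats["Variance"] == 0.0
        assert feats["Uniformity"] == 1.0
        assert feats["Entropy"] == 0.0
        assert feats["Skewness"] == 0.0 and "Skewness" in deg
        assert feats["Kurtosis"] == 0.0 and "Kurtosis" in deg
        assert feats["TotalEnergy"] == pytest.approx(2.0 * 20 * 49.0)

    def test_four_equal_bins_entropy_two_bits(self):
        values = [0.0] * 5 + [30.0] * 5 + [60.0] * 5 + [90.0] * 5
        feats, _ = first_order_features(values, bin_width=25)
        assert feats["Entropy"] == pytest.approx(2.0)
        assert feats["Uniformity"] == pytest.approx(0.25)

    def test_returns_exactly_18_values(self, rng):
        feats, _ = first_order_features(rng.normal(size=100))
        assert len(feats) == 18
        assert set(feats) == set(FIRSTORDER_NAMES)

    def test_moments_match_scipy(self, rng):
        from scipy import stats as sps
        x = rng.normal(10, 3, size=500)
        feats, _ = first_order_features(x)
        assert feats["Skewness"] == pytest.approx(sps.skew(x, bias=True))
        assert feats["Kurtosis"] == pytest.approx(
            sps.kurtosis(x, bias=True, fisher=False))
        assert feats["Variance"] == pytest.approx(np.var(x))
        assert feats["MeanAbsoluteDeviation"] == pytest.approx(
            np.abs(x - x.mean()).mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            first_order_features([])


def _droi(levels):
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim < 3:
        levels = levels.reshape(levels.shape + (1,) * (3 - levels.ndim))
    return DiscretizedRoi(levels=levels, ng=int(levels.max()),
                          spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="module")
def random_droi():
    rng = np.random.default_rng(7)
    return _droi(rng.integers(1, 5, size=(6, 6, 4)))


class TestFamilyCardinalities:

    def test_family_sizes(self, random_droi):
        assert len(glcm_features(random_droi)[0]) == 24
        assert len(glrlm_features(random_droi)[0]) == 16
        assert len(glszm_features(random_droi)[0]) == 16
        assert len(gldm_features(random_droi)[0]) == 14
        assert len(ngtdm_features(random_droi)[0]) == 5

    def test_total_schema_is_93_unique_names(self):
        assert len(FEATURE_NAMES) == 93
        assert len(set(FEATURE_NAMES)) == 93
        assert sum(FAMILY_SIZES.values()) == 93


class TestDegenerateCases:
    def test_constant_roi_glcm(self):
        d = _droi(np.ones((3, 3, 3), int))
        feats, deg = glcm_features(d)
        assert feats["JointEntropy"] == 0.0
        assert feats["MaximumProbability"] == 1.0
        assert feats["Correlation"] == 1.0 and "Correlation" in deg

    def test_constant_roi_ngtdm(self):
        d = _droi(np.ones((3, 3, 3), int))
        feats, _ = ngtdm_features(d)
        assert feats["Contrast"] == 0.0
        assert feats["Busyness"] == 0.0

    def test_uniform_cube_single_zone(self):
        d = _droi(np.ones((4, 4, 4), int))
        feats, _ = glszm_features(d)
        assert feats["ZonePercentage"] == pytest.approx(1.0 / 64)
        assert feats["LargeAreaEmphasis"] == pytest.approx(64.0 ** 2)

    def test_8_phase_pattern_all_zones_size_one(self):
        # 8 interleaved levels: equal levels are never 26-adjacent, so
        # every zone is a single voxel
        i, j, k = np.indices((4, 4, 4))
        d = _droi(1 + (i % 2) + 2 * (j % 2) + 4 * (k % 2))
        feats, _ = glszm_features(d)
        assert feats["SmallAreaEmphasis"] == pytest.approx(1.0)
        assert feats["ZonePercentage"] == pytest.approx(1.0)

    def test_3d_checkerboard_has_two_diagonal_zones(self):
        # under 26-connectivity the two parity classes of a checkerboard
        # are diagonally connected: exactly 2 zones of 32 voxels
        idx = np.indices((4, 4, 4)).sum(axis=0)
        d = _droi((idx % 2) + 1)
        feats, _ = glszm_features(d)
        assert feats["ZonePercentage"] == pytest.approx(2.0 / 64)
        assert feats["LargeAreaEmphasis"] == pytest.approx(32.0 ** 2)

    def test_constant_row_run_percentage(self):
        d = _droi(np.ones((5, 1, 1), int))
        feats, _ = glrlm_features(d)
        # along the row direction: a single run of length 5 (RP=1/5);
        # 12 other directions see 5 runs of length 1 (RP=1)
        expected = (1 / 5 + 12 * 1.0) / 13
        assert feats["RunPercentage"] == pytest.approx(expected)


@pytest.fixture(scope="module")
def image_and_mask():
    rng = np.random.default_rng(11)
    vals = rng.normal(50, 30, size=(10, 10, 6))
    img = VolumeImage(vals, (0.78, 0.78, 1.0))
    mask = np.zeros(vals.shape, bool)
    mask[2:8, 2:8, 1:5] = True
    return img, mask


class TestExtractFeatureVector:

    def test_93_features_no_shape_family(self, image_and_mask):
        fv = extract_feature_vector(*image_and_mask)
        assert len(fv) == 93
        assert not any(n.startswith("shape") for n in fv)

    def test_deterministic(self, image_and_mask):
        img, mask = image_and_mask
        assert extract_feature_vector(img, mask) == \
            extract_feature_vector(img, mask)

    def test_gray_level_shift_invariance(self, image_and_mask):
        img, mask = image_and_mask
        a = extract_feature_vector(img, mask)
        shifted = VolumeImage(np.asarray(img.values) + 137.0, img.spacing)
        b = extract_feature_vector(shifted, mask)
        for name in FEATURE_NAMES:
            if name.split("_")[0] == "firstorder":
                continue  # first-order features shift by design
            assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_translation_invariance(self, image_and_mask):
        img, mask = image_and_mask
        a = extract_feature_vector(img, mask)
        vals = np.roll(np.asarray(img.values), (1, 2, 1), axis=(0, 1, 2))
        rolled_mask = np.roll(mask, (1, 2, 1), axis=(0, 1, 2))
        b = extract_feature_vector(VolumeImage(vals, img.spacing),
                                   rolled_mask)
        for name in FEATURE_NAMES:
            assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_constant_roi_degenerate_contract(self):
        img = VolumeImage(np.full((6, 6, 6), -120.0), (1, 1, 1))
        mask = np.ones((6, 6, 6), bool)
        fv = extract_feature_vector(img, mask)
        assert fv["glcm_Correlation"] == 1.0
        assert fv.is_degenerate("glcm_Correlation")
        assert fv["firstorder_Skewness"] == 0.0
        assert fv.is_degenerate("firstorder_Skewness")
        assert fv["ngtdm_Coarseness"] == 1e6
        assert fv.is_degenerate("ngtdm_Coarseness")

    def test_empty_mask_rejected(self, image_and_mask):
        img, _ = image_and_mask
        with pytest.raises(ValueError):
            extract_feature_vector(img, np.zeros(img.shape, bool))

    def test_mask_shape_mismatch_rejected(self, image_and_mask):
        img, _ = image_and_mask
        with pytest.raises(ValueError):
            extract_feature_vector(img, np.ones((2, 2, 2), bool))

    def test_2d_mode_differs_but_is_complete(self, image_and_mask):
        img, mask = image_and_mask
        fv3 = extract_feature_vector(img, mask)
        fv2 = extract_feature_vector(
            img, mask, ExtractionSettings(dimensionality="twoD_per_slice"))
        assert len(fv2) == 93
        assert fv2["glcm_Contrast"] != pytest.approx(fv3["glcm_Contrast"])


class TestProbabilityNormalization:
    def test_glcm_probabilities_sum_to_one(self, rng):
        from phantomrad.features.matrices import (glcm_matrix,
                                                  unique_directions)
        levels = rng.integers(1, 5, size=(5, 5, 3))
        for d in unique_directions():
            P = glcm_matrix(levels, 4, d)
            if P.sum() > 0:
                assert (P / P.sum()).sum() == pytest.approx(1.0, abs=1e-10)
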