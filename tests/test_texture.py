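import logging

import numpy as np
import pytest

from gliomics.config import TransformBankConfig
from gliomics.imgproc import ImageVolume
from gliomics.texture import (
    FeatureName,
    GLCM_DIRECTIONS,
    encode_feature_name,
    extract_feature_table,
    feature_manifest,
    firstorder_features,
    glcm_features,
    glcm_matrices,
    gldm_features,
    gldm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
    parse_feature_name,
)
from oracles import brute_glcm, brute_gldm, brute_glszm, brute_ngtdm


def random_case(rng, max_levels=4):
    shape = tuple(rng.integers(2, (6, 6, 4)))
    ng = int(rng.integers(1, max_levels + 1))
    gray = rng.integers(1, ng + 1, shape)
    roi = rng.random(shape) < 0.7
    if not roi.any():
        roi.flat[0] = True
    gray = gray * roi
    return gray, roi, ng


class TestFeatureNames:
    def test_example_name_round_trip(self):
        name = "T2-wavelet-LHL_glszm_SizeZoneNonUniformityNormalized"
        parsed = parse_feature_name(name)
        assert parsed == FeatureName(
            "T2", "wavelet-LHL", "glszm", "SizeZoneNonUniformityNormalized"
        )
        assert str(parsed) == name

    @pytest.mark.parametrize(
        "name",
        [
            "T1pre-lbp-3D-m1_glcm_Correlation",
            "T1post-lbp-2D_glcm_Imc2",
            "FLAIR-gradient_firstorder_Kurtosis",
            "T1pre-exponential_glszm_HighGrayLevelZoneEmphasis",
        ],
    )
    def test_published_style_names_parse(self, name):
        parsed = parse_feature_name(name)
        assert str(parsed) == name

    def test_bad_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_feature_name("T9", "original", "glcm", "Correlation")
        with pytest.raises(ValueError):
            parse_feature_name("T9-original_glcm_Correlation")


class TestFirstOrder:
    def test_median_minimum(self):
        vol = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        roi = np.ones_like(vol, dtype=bool)
        feats = firstorder_features(vol, roi)
        assert feats["Median"] == 2.0
        assert feats["Minimum"] == 1.0

    def test_normal_kurtosis_is_three(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((50, 50, 40))
        roi = np.ones_like(vol, dtype=bool)
        feats = firstorder_features(vol, roi)
        assert feats["Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_constant_roi_kurtosis_sentinel(self):
        vol = np.full((3, 3, 3), 5.0)
        roi = np.ones_like(vol, dtype=bool)
        feats = firstorder_features(vol, roi)
        assert feats["Kurtosis"] == 0.0
        assert feats["Variance"] == 0.0

    def test_ignores_outside_roi(self, rng):
        vol = rng.normal(0, 1, (5, 5, 5))
        roi = np.zeros_like(vol, dtype=bool)
        roi[1:4, 1:4, 1:4] = True
        feats = firstorder_features(vol, roi)
        vol2 = vol.copy()
        vol2[~roi] = 999.0
        assert firstorder_features(vol2, roi) == feats

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            firstorder_features(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestGLCM:
    def test_constant_roi_degenerate_conventions(self):
        gray = np.ones((3, 3, 2), dtype=int)
        roi = np.ones_like(gray, dtype=bool)
        feats = glcm_features(gray, roi, ng=1)
        assert feats["Correlation"] == 1.0
        assert feats["Imc2"] == 0.0

    def test_checkerboard_single_axis_correlation(self):
        i, j = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        board = ((i + j) % 2 + 1)[:, :, None]  # levels 1/2
        roi = np.ones_like(board, dtype=bool)
        feats = glcm_features(board, roi, ng=2, directions=[(1, 0, 0)])
        assert feats["Correlation"] == pytest.approx(-1.0)

    def test_matrix_equals_bruteforce(self, rng):
        for _ in range(30):
            gray, roi, ng = random_case(rng)
            mats = glcm_matrices(gray, roi, ng)
            expected = [
                m for d in GLCM_DIRECTIONS
                if (m := brute_glcm(gray, roi, ng, d)) is not None
            ]
            assert len(mats) == len(expected)
            for got, exp in zip(mats, expected):
                np.testing.assert_allclose(got, exp, atol=1e-12)


class TestGLSZM:
    def test_single_zone_sznn_is_one(self):
        gray = np.ones((3, 3, 3), dtype=int)
        roi = np.ones_like(gray, dtype=bool)
        assert glszm_features(gray, roi, 1)["SizeZoneNonUniformityNormalized"] == 1.0

    def test_two_zone_hand_case(self):
        # zone of size 1 (level 2) + zone of size 2 (level 1)
        gray = np.zeros((3, 1, 1), dtype=int)
        roi = np.ones_like(gray, dtype=bool)
        gray[:, 0, 0] = [1, 1, 2]
        feats = glszm_features(gray, roi, 2)
        assert feats["SizeZoneNonUniformityNormalized"] == pytest.approx(0.5)

    def test_sznn_decreases_with_zone_diversity(self):
        # equal zone sizes -> SZNN = 0.5; diverse sizes -> lower
        equal = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        roi = np.ones_like(equal, dtype=bool)
        sznn_eq = glszm_features(equal, roi, 2)["SizeZoneNonUniformityNormalized"]
        diverse = np.array([1, 1, 1, 2, 1, 1]).reshape(6, 1, 1)
        roi6 = np.ones_like(diverse, dtype=bool)
        sznn_div = glszm_features(diverse, roi6, 2)[
            "SizeZoneNonUniformityNormalized"
        ]
        # three zones of sizes 3,1,2 vs two zones of equal size
        assert sznn_div < sznn_eq + 1e-12

    def test_zone_inventory_equals_floodfill(self, rng):
        for _ in range(30):
            gray, roi, ng = random_case(rng)
            np.testing.assert_array_equal(
                glszm_matrix(gray, roi, ng), brute_glszm(gray, roi, ng)
            )


class TestGLDM:
    def test_single_voxel_roi(self):
        gray = np.ones((3, 3, 3), dtype=int)
        roi = np.zeros_like(gray, dtype=bool)
        roi[1, 1, 1] = True
        mat = gldm_matrix(gray, roi, 1)
        assert mat[0, 0] == 1  # dependence 0
        feats = gldm_features(gray, roi, 1)
        assert feats["DependenceNonUniformityNormalized"] == 1.0

    def test_constant_3x3x1_hand_case(self):
        gray = np.ones((3, 3, 1), dtype=int)
        roi = np.ones_like(gray, dtype=bool)
        mat = gldm_matrix(gray, roi, 1)
        # corners 3 neighbors, edges 5, center 8
        assert mat[0, 3] == 4 and mat[0, 5] == 4 and mat[0, 8] == 1
        feats = gldm_features(gray, roi, 1)
        assert feats["DependenceNonUniformityNormalized"] == pytest.approx(33 / 81)

    def test_matrix_equals_bruteforce(self, rng):
        for _ in range(30):
            gray, roi, ng = random_case(rng)
            alpha = int(rng.integers(0, 2))
            np.testing.assert_array_equal(
                gldm_matrix(gray, roi, ng, alpha=alpha),
                brute_gldm(gray, roi, ng, alpha=alpha),
            )


class TestNGTDM:
    def test_constant_roi_conventions(self):
        gray = np.ones((3, 3, 2), dtype=int)
        roi = np.ones_like(gray, dtype=bool)
        feats = ngtdm_features(gray, roi, 1)
        assert feats["Busyness"] == 0.0
        assert feats["Strength"] == 0.0

    def test_striped_hand_case(self):
        # 4x4x1 alternating-column stripes of levels 1 and 2
        gray = np.tile(np.array([1, 2, 1, 2]), (4, 1))[:, :, None]
        roi = np.ones_like(gray, dtype=bool)
        n_g, s_g = ngtdm_table(gray, roi, 2)
        exp_n, exp_s = brute_ngtdm(gray, roi, 2)
        np.testing.assert_allclose(n_g, exp_n)
        np.testing.assert_allclose(s_g, exp_s)
        assert n_g.tolist() == [8, 8]
        # spot-check one voxel by hand: corner (0,0) level 1 has neighbors
        # (0,1)=2,(1,0)=1,(1,1)=2 -> mean 5/3, diff 2/3
        assert s_g[0] > 0

    def test_table_equals_bruteforce(self, rng):
        for _ in range(30):
            gray, roi, ng = random_case(rng)
            n_g, s_g = ngtdm_table(gray, roi, ng)
            exp_n, exp_s = brute_ngtdm(gray, roi, ng)
            np.testing.assert_allclose(n_g, exp_n, atol=1e-10)
            np.testing.assert_allclose(s_g, exp_s, atol=1e-10)


class TestMaskLocality:
    @pytest.mark.parametrize("family", ["glcm", "glszm", "gldm", "ngtdm"])
    def test_features_invariant_outside_roi(self, family, rng):
        from gliomics import texture as tx

        fn = {
            "glcm": tx.glcm_features,
            "glszm": tx.glszm_features,
            "gldm": tx.gldm_features,
            "ngtdm": tx.ngtdm_features,
        }[family]
        gray, roi, ng = random_case(rng)
        base = fn(gray, roi, ng)
        tampered = gray.copy()
        tampered[~roi] = ng  # junk outside ROI
        assert fn(tampered, roi, ng) == base


class TestExtraction:
    def test_minimal_config_four_columns(self, small_images, minimal_transforms):
        volumes, masks = small_images
        one = {k: volumes[k] for k in list(volumes)[:2]}
        df = extract_feature_table(
            one, masks, minimal_transforms, families=("firstorder",)
        )
        median_cols = [c for c in df.columns if c.endswith("_Median")]
        assert len(median_cols) == 4  # one per sequence

    def test_manifest_arithmetic(self, minimal_transforms):
        cols = feature_manifest(minimal_transforms, families=("firstorder",))
        assert len(cols) == 4 * 1 * 16  # 4 sequences x 1 transform x 16 features
        full = feature_manifest(TransformBankConfig())
        n_transforms = len(TransformBankConfig().transform_labels())
        per_image = 16 + 8 + 15 + 10 + 5
        assert len(full) == 4 * n_transforms * per_image

    def test_extraction_matches_manifest(self, small_images, minimal_transforms):
        volumes, masks = small_images
        one = {k: volumes[k] for k in list(volumes)[:1]}
        df = extract_feature_table(one, masks, minimal_transforms)
        assert set(df.columns) == set(feature_manifest(minimal_transforms))

    def test_missing_sequence_skipped_with_log(
        self, small_images, minimal_transforms, caplog
    ):
        volumes, masks = small_images
        pids = list(volumes)[:2]
        broken = {pids[0]: dict(volumes[pids[0]]), pids[1]: dict(volumes[pids[1]])}
        del broken[pids[0]]["T2"]
        with caplog.at_level(logging.WARNING, logger="gliomics.texture"):
            df = extract_feature_table(
                broken, masks, minimal_transforms, families=("firstorder",)
            )
        assert pids[0] not in df.index and pids[1] in df.index
        assert any("missing sequence" in r.message for r in caplog.records)

    def test_deterministic(self, small_images, minimal_transforms):
        volumes, masks = small_images
        one = {k: volumes[k] for k in list(volumes)[:1]}
        a = extract_feature_table(one, masks, minimal_transforms)
        b = extract_feature_table(one, masks, minimal_transforms)
        assert a.equals(b)
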