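import numpy as np
import pytest

from maskvar.errors import DataError, UsageError
from maskvar.features import (
    FEATURE_FAMILIES,
    ExtractionConfig,
    GreyLevelVolume,
    build_texture_matrix,
    discretise,
    extract_features,
    feature_family,
)
from maskvar.geometry import ImageVolume
from maskvar.rasterize import BinaryMask, RasterStrategy

import oracles
from conftest import axis_aligned_geometry


def _volume(data, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=float)
    geom = axis_aligned_geometry(spacing=spacing, dims=data.shape)
    return ImageVolume(geometry=geom, voxels=data, modality_tag="T")


def _mask(shape_or_bool, spacing=(1.0, 1.0, 1.0)):
    if isinstance(shape_or_bool, tuple):
        vox = np.ones(shape_or_bool, dtype=bool)
    else:
        vox = np.asarray(shape_or_bool, dtype=bool)
    geom = axis_aligned_geometry(spacing=spacing, dims=vox.shape)
    return BinaryMask(geometry=geom, voxels=vox, strategy=RasterStrategy(method="centre"))


def _gvol(levels, ng=None):
    levels = np.asarray(levels, dtype=int)
    mask = _mask(levels > 0)
    return GreyLevelVolume(levels=levels, Ng=ng or int(levels.max()), mask=mask)


class TestDiscretise:
    def test_fbn_two_bins(self):
        img = _volume(np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1, 1))
        gv = discretise(img, _mask((4, 1, 1)), ExtractionConfig("FBN", n_bins=2))
        assert gv.levels.ravel().tolist() == [1, 1, 2, 2]

    def test_fbn_matches_brute_force_binning(self):
        rng = np.random.default_rng(11)
        data = rng.uniform(-50, 120, size=(4, 4, 3))
        img = _volume(data)
        ng = 6
        gv = discretise(img, _mask((4, 4, 3)), ExtractionConfig("FBN", n_bins=ng))
        lo, hi = data.min(), data.max()
        edges = lo + (hi - lo) * np.arange(1, ng) / ng
        expected = 1 + np.searchsorted(edges, data, side="right")
        expected = np.minimum(expected, ng)
        assert np.array_equal(gv.levels, expected)

    def test_constant_region_single_level(self):
        img = _volume(np.full((3, 3, 1), 7.0))
        gv = discretise(img, _mask((3, 3, 1)), ExtractionConfig("FBN", n_bins=8))
        assert (gv.levels == 1).all()

    def test_fbs_level(self):
        img = _volume(np.array([[[50.0]]]))
        gv = discretise(
            img, _mask((1, 1, 1)), ExtractionConfig("FBS", bin_width=25.0, min_bound=0.0)
        )
        assert gv.levels[0, 0, 0] == 3

    def test_empty_mask_rejected(self):
        img = _volume(np.zeros((2, 2, 2)))
        empty = _mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(DataError):
            discretise(img, empty, ExtractionConfig())


@pytest.mark.parametrize("kind,oracle", [
    ("cm", oracles.glcm_oracle),
    ("rlm", oracles.glrlm_oracle),
    ("szm", oracles.glszm_oracle),
    ("dzm", oracles.gldzm_oracle),
    ("ngt", oracles.ngtdm_oracle),
    ("ngl", oracles.ngldm_oracle),
])
class TestTextureMatricesAgainstOracle:
    def test_random_small_volumes(self, kind, oracle):
        rng = np.random.default_rng(17)
        for _ in range(6):
            ng = int(rng.integers(2, 5))
            levels = rng.integers(1, ng + 1, size=(4, 4, 3))
            mask = rng.random((4, 4, 3)) < 0.8
            levels = np.where(mask, levels, 0)
            if not mask.any():
                continue
            gv = GreyLevelVolume(levels=levels, Ng=ng, mask=_mask(mask))
            got = build_texture_matrix(gv, kind)
            want = oracle(levels, mask, ng)
            assert got.shape == want.shape
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_two_by_two_plane(self, kind, oracle):
        levels = np.array([[1, 1], [2, 2]]).reshape(2, 2, 1)
        mask = np.ones((2, 2, 1), dtype=bool)
        gv = GreyLevelVolume(levels=levels, Ng=2, mask=_mask(mask))
        np.testing.assert_allclose(
            build_texture_matrix(gv, kind), oracle(levels, mask, 2), atol=1e-12
        )


class TestTextureMatrixEdges:
    def test_unknown_kind_rejected(self):
        gv = _gvol(np.ones((2, 2, 1), dtype=int))
        with pytest.raises(UsageError):
            build_texture_matrix(gv, "glrlm3d")

    def test_single_voxel_run_and_zone(self):
        levels = np.zeros((3, 3, 1), dtype=int)
        levels[1, 1, 0] = 1
        gv = _gvol(levels, ng=1)
        R = build_texture_matrix(gv, "rlm")
        # 13 directions each see one run of length 1
        assert R.shape == (1, 1) and R[0, 0] == 13
        S = build_texture_matrix(gv, "szm")
        assert S.shape == (1, 1) and S[0, 0] == 1

    def test_constant_plane_dependence_counts(self):
        levels = np.ones((3, 3, 1), dtype=int)
        gv = _gvol(levels)
        D = build_texture_matrix(gv, "ngl")
        want = oracles.ngldm_oracle(levels, np.ones((3, 3, 1), bool), 1)
        np.testing.assert_allclose(D, want)
        # corner voxels have 3 same-level neighbours, centre has 8
        assert D[0, 3] == 4 and D[0, 8] == 1


class TestExtractFeatures:
    def test_single_voxel_morphology(self):
        img = _volume(np.full((3, 3, 3), 5.0), spacing=(2, 2, 2))
        vox = np.zeros((3, 3, 3), dtype=bool)
        vox[1, 1, 1] = True
        fv = extract_features(img, _mask(vox, spacing=(2, 2, 2)), ExtractionConfig())
        assert fv["morph_volume"] == pytest.approx(8.0)
        assert fv["morph_surface_area"] == pytest.approx(24.0)
        assert fv["morph_max_diameter"] == 0.0

    def test_constant_region_degenerate_limits(self):
        img = _volume(np.full((3, 3, 2), 4.2))
        fv = extract_features(img, _mask((3, 3, 2)), ExtractionConfig())
        assert fv["stat_variance"] == 0.0
        assert fv["ih_entropy"] == 0.0
        assert fv["ih_uniformity"] == 1.0
        assert fv["cm_joint_max"] == 1.0

    def test_every_family_represented(self):
        rng = np.random.default_rng(2)
        img = _volume(rng.normal(size=(5, 5, 3)))
        fv = extract_features(img, _mask((5, 5, 3)), ExtractionConfig(n_bins=4))
        fams = fv.families()
        for fam in FEATURE_FAMILIES:
            assert len(fams[fam]) >= 3, fam

    def test_checkerboard_against_matrix_oracles(self):
        levels = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]]).reshape(3, 3, 1)
        mask = np.ones((3, 3, 1), dtype=bool)
        # drive the full extractor with intensities that discretise (FBN 2)
        # to exactly this level pattern
        img = _volume(levels.astype(float))
        fv = extract_features(img, _mask(mask), ExtractionConfig("FBN", n_bins=2))

        M = oracles.glcm_oracle(levels, mask, 2)
        P = M / M.sum()
        i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
        assert fv["cm_joint_max"] == pytest.approx(P.max())
        assert fv["cm_contrast"] == pytest.approx(((i - j) ** 2 * P).sum())
        assert fv["cm_dissimilarity"] == pytest.approx((abs(i - j) * P).sum())

        R = oracles.glrlm_oracle(levels, mask, 2)
        ns = R.sum()
        jr = np.arange(1, R.shape[1] + 1)
        assert fv["rlm_short_run_emphasis"] == pytest.approx(
            (R.sum(0) / jr**2).sum() / ns
        )
        assert fv["rlm_run_percentage"] == pytest.approx(ns / 9)

        S = oracles.glszm_oracle(levels, mask, 2)
        js = np.arange(1, S.shape[1] + 1)
        assert fv["szm_small_zone_emphasis"] == pytest.approx(
            (S.sum(0) / js**2).sum() / S.sum()
        )

        D = oracles.gldzm_oracle(levels, mask, 2)
        jd = np.arange(1, D.shape[1] + 1)
        assert fv["dzm_small_distance_emphasis"] == pytest.approx(
            (D.sum(0) / jd**2).sum() / D.sum()
        )

        ps = oracles.ngtdm_oracle(levels, mask, 2)
        assert fv["ngt_coarseness"] == pytest.approx(
            1.0 / (ps[:, 0] * ps[:, 1]).sum()
        )

        L = oracles.ngldm_oracle(levels, mask, 2)
        jl = np.arange(1, L.shape[1] + 1)
        assert fv["ngl_low_dependence_emphasis"] == pytest.approx(
            (L.sum(0) / jl**2).sum() / L.sum()
        )


class TestFeatureInvariants:
    def test_probability_matrices_sum_to_one(self):
        rng = np.random.default_rng(23)
        levels = rng.integers(1, 5, size=(5, 5, 3))
        mask = rng.random((5, 5, 3)) < 0.9
        levels = np.where(mask, levels, 0)
        gv = GreyLevelVolume(levels=levels, Ng=4, mask=_mask(mask))
        for kind in ("cm", "rlm", "szm", "dzm", "ngl"):
            M = build_texture_matrix(gv, kind)
            P = M / M.sum()
            assert abs(P.sum() - 1.0) < 1e-12
        ps = build_texture_matrix(gv, "ngt")
        assert abs(ps[:, 0].sum() - 1.0) < 1e-12

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(29)
        data = rng.normal(size=(5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[2, 2, 4] = True  # break symmetry
        fv = extract_features(
            _volume(data), _mask(mask), ExtractionConfig(n_bins=4)
        )
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            fvp = extract_features(
                _volume(np.transpose(data, perm)),
                _mask(np.transpose(mask, perm)),
                ExtractionConfig(n_bins=4),
            )
            for key, val in fv.values.items():
                assert fvp[key] == pytest.approx(val, rel=1e-9), key

    def test_intensity_shift_invariance_fbn(self):
        rng = np.random.default_rng(31)
        data = rng.normal(size=(4, 4, 3))
        cfg = ExtractionConfig(n_bins=4)
        fv1 = extract_features(_volume(data), _mask((4, 4, 3)), cfg)
        fv2 = extract_features(_volume(data + 37.5), _mask((4, 4, 3)), cfg)
        for key, val in fv1.values.items():
            fam = feature_family(key)
            if fam in ("ih", "cm", "rlm", "szm", "dzm", "ngt", "ngl"):
                assert fv2[key] == pytest.approx(val, rel=1e-9), key
        assert fv2["stat_mean"] == pytest.approx(fv1["stat_mean"] + 37.5)

    def test_volume_sensitivity_to_one_voxel(self):
        rng = np.random.default_rng(37)
        data = rng.normal(size=(5, 5, 3))
        mask = np.zeros((5, 5, 3), dtype=bool)
        mask[1:4, 1:4, 0:3] = True  # 27 voxels
        mask[0, 0, 0] = True
        mask[0, 1, 0] = True
        mask[0, 2, 0] = True  # 30 voxels
        fv30 = extract_features(_volume(data), _mask(mask), ExtractionConfig())
        mask2 = mask.copy()
        mask2[0, 2, 0] = False
        fv29 = extract_features(_volume(data), _mask(mask2), ExtractionConfig())
        assert fv30["morph_volume"] - fv29["morph_volume"] == pytest.approx(1.0)
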