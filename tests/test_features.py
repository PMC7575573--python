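"""Feature panel: discretization, hand-computed examples, oracle equality,
Gabor responses, and the 200-feature lesion vector."""

import numpy as np
import pytest

import rimradiomics as rr
import rimradiomics.features as ft
from _oracles import FAMILY_ORACLES


def _region_from_array(arr, n_bins=32):
    mask = np.ones(np.asarray(arr).shape, dtype=np.uint8)
    return ft.discretize_region(np.asarray(arr, dtype=float), mask, n_bins)


def _strip(values):
    """Embed a 1D level strip in a 3x3xN block of padding-free mask."""
    arr = np.zeros((1, 1, len(values)), dtype=float)
    arr[0, 0, :] = values
    return arr


class TestDiscretize:
    def test_identity_binning_of_32_values(self):
        arr = np.arange(32, dtype=float).reshape(2, 4, 4)
        region = _region_from_array(arr, n_bins=32)
        np.testing.assert_array_equal(np.sort(region.levels_in_mask),
                                      np.arange(1, 33))

    def test_constant_region_maps_to_level_1(self):
        region = _region_from_array(np.full((3, 3, 3), 7.0))
        assert set(region.levels_in_mask) == {1}

    def test_two_values_two_bins(self):
        arr = np.zeros((3, 3, 3))
        arr[0, 0, 0] = 10.0
        region = _region_from_array(arr, n_bins=2)
        assert set(region.levels_in_mask) == {1, 2}
        assert region.levels_in_mask.sum() == 26 + 2 * 1

    def test_small_region_rejected(self):
        with pytest.raises(ft.LesionTooSmallError):
            _region_from_array(np.zeros((2, 2, 2)))

    def test_too_few_bins_rejected(self):
        with pytest.raises(rr.ValidationError):
            _region_from_array(np.zeros((3, 3, 3)), n_bins=1)


class TestFirstOrder:
    def test_hand_computed_moments(self):
        vals = np.array([2, 4, 4, 4, 5, 5, 7, 9], dtype=float)
        arr = np.zeros((2, 2, 2))
        arr.flat[:] = vals
        f = ft.first_order_features(arr, np.ones((2, 2, 2), dtype=np.uint8))
        assert f["mean"] == pytest.approx(5.0)
        assert f["variance"] == pytest.approx(4.0)   # population variance
        assert f["energy"] == pytest.approx(np.sum(vals ** 2))

    def test_constant_region_degenerate_conventions(self):
        f = ft.first_order_features(np.full((3, 3, 3), 5.0),
                                    np.ones((3, 3, 3), dtype=np.uint8))
        assert f["variance"] == 0
        assert f["entropy"] == 0
        assert f["skewness"] == 0
        assert f["uniformity"] == 1

    def test_median_interpolates(self):
        arr = np.zeros((1, 2, 2))
        arr.flat[:] = [1, 2, 3, 4]
        f = ft.first_order_features(arr, np.ones((1, 2, 2), dtype=np.uint8))
        assert f["median"] == pytest.approx(2.5)
        assert f["iqr"] == pytest.approx(f["p75"] - f["p25"])

    def test_exactly_19_features(self):
        f = ft.first_order_features(np.zeros((3, 3, 3)),
                                    np.ones((3, 3, 3), dtype=np.uint8))
        assert len(f) == 19


class TestGLCMExamples:
    def test_strip_1122_hand_enumeration(self):
        """Along the strip axis: pairs (1,1),(1,2),(2,2); symmetric counts 2
        each of 6 -> p(1,1)=p(2,2)=1/3, p(1,2)=p(2,1)=1/6, contrast 1/3."""
        arr = _strip([0, 0, 10, 10])
        mask = np.ones(arr.shape, dtype=np.uint8)
        # bypass the size gate for this 4-voxel didactic example
        region = ft.DiscretizedRegion(
            np.where(mask > 0, ft._bin_levels(arr[mask > 0], 2), 0
                     ).reshape(arr.shape),
            mask > 0, 2, np.array([0.0, 5.0, 10.0]))
        mats = ft.glcm_matrices(region)
        along = [m for m in mats if m.meta["direction"] == (0, 0, 1)][0]
        P = along.values / along.values.sum()
        np.testing.assert_allclose(P, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        assert ft._glcm_stats(P)["contrast"] == pytest.approx(1 / 3)

    def test_constant_region_contrast_zero_energy_one(self):
        region = _region_from_array(np.full((3, 3, 3), 4.0))
        f = ft.glcm_features(region)
        assert f["contrast"] == 0
        assert f["joint_energy"] == 1
        assert f["correlation"] == 0   # zero-variance convention


class TestGLRLMExamples:
    def test_strip_runs_hand_enumeration(self):
        arr = _strip([0, 0, 0, 10])
        mask = np.ones(arr.shape, dtype=np.uint8)
        region = ft.DiscretizedRegion(
            np.where(mask > 0, ft._bin_levels(arr[mask > 0], 2), 0
                     ).reshape(arr.shape),
            mask > 0, 2, np.array([0.0, 5.0, 10.0]))
        mats = ft.glrlm_matrices(region)
        along = [m for m in mats if m.meta["direction"] == (0, 0, 1)][0].values
        assert along[0, 2] == 1     # level 1, run length 3
        assert along[1, 0] == 1     # level 2, run length 1
        assert along.sum() == 2

    def test_constant_strip_run_percentage(self):
        region = _region_from_array(np.full((3, 3, 3), 1.0))
        f = ft.glrlm_features(region)
        # one run per direction through each line; run percentage averages
        # runs/voxels over the 13 directions
        assert 0 < f["run_percentage"] < 1


class TestGLSZMExamples:
    def test_two_disjoint_blobs_sizes_3_and_5(self):
        arr = np.zeros((3, 3, 7))
        arr[:, :, :] = 0.0
        # two same-level zones separated by a plane of the other level
        arr[1, 1, 0:3] = 10.0          # would merge with diagonal contact
        arr[1, 1, 4:7] = 10.0
        arr[0, 0, 4:6] = 10.0
        region = _region_from_array(arr, n_bins=2)
        mat = ft.glszm_matrix(region).values
        # level-2 zones: one of size 3 and one 26-connected of size 5
        assert mat[1, 2] == 1
        assert mat[1, 4] == 1


class TestNGTDMDegenerate:
    def test_constant_region_coarseness_convention(self):
        region = _region_from_array(np.full((3, 3, 3), 2.0))
        f = ft.ngtdm_features(region)
        assert f["coarseness"] == ft.COARSENESS_DEGENERATE
        assert f["contrast"] == 0


class TestOracleEquality:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_families_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 7, size=3))
        mask = rng.random(shape) < 0.85
        mask.flat[: max(0, 27 - mask.sum())] = True
        vals = rng.normal(50, 15, size=shape)
        region = ft.discretize_region(vals, mask.astype(np.uint8), n_bins=6)
        levels = np.where(region.mask, region.levels, 0)
        impls = {
            "glcm": ft.glcm_features(region),
            "glrlm": ft.glrlm_features(region),
            "glszm": ft.glszm_features(region),
            "ngtdm": ft.ngtdm_features(region),
            "ngldm": ft.ngldm_features(region),
        }
        for fam, impl in impls.items():
            oracle = FAMILY_ORACLES[fam](levels)
            for k in impl:
                assert impl[k] == pytest.approx(oracle[k], abs=1e-10), \
                    f"{fam}.{k}"

    def test_normalized_matrices_and_ranges(self, rng):
        vals = rng.normal(0, 1, size=(6, 6, 6))
        region = ft.discretize_region(vals, np.ones((6, 6, 6), np.uint8), 8)
        for tm in ft.glcm_matrices(region):
            P = tm.normalized()
            assert P.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(P >= 0)
        f = ft.glcm_features(region)
        assert 0 < f["joint_energy"] <= 1
        assert -1 <= f["correlation"] <= 1


class TestGabor:
    def test_constant_image_zero_response(self):
        vol = np.full((12, 12, 5), 100.0)
        mask = np.ones(vol.shape, dtype=np.uint8)
        f = ft.gabor_features(vol, mask)
        assert all(abs(v) < 1e-8 for v in f.values())

    def test_grating_peaks_at_matching_bank_element(self):
        x = np.arange(40)
        grating = np.sin(2 * np.pi * x / 4.0)
        vol = np.repeat(grating[:, None], 40, axis=1)[:, :, None] * np.ones(5)
        mask = np.zeros(vol.shape, dtype=np.uint8)
        mask[8:32, 8:32, :] = 1
        f = ft.gabor_features(vol, mask)
        assert max(f, key=f.get) == "mean_o0_w4"

    def test_rotated_grating_maps_to_rotated_orientation(self):
        x = np.arange(40)
        grating = np.sin(2 * np.pi * x / 4.0)
        vol0 = np.repeat(grating[:, None], 40, axis=1)[:, :, None] * np.ones(3)
        vol90 = np.transpose(vol0, (1, 0, 2))
        mask = np.zeros(vol0.shape, dtype=np.uint8)
        mask[8:32, 8:32, :] = 1
        f0 = ft.gabor_features(vol0, mask)
        f90 = ft.gabor_features(vol90, mask)
        assert f0["mean_o0_w4"] == pytest.approx(f90["mean_o90_w4"], rel=1e-6)
        assert max(f90, key=f90.get) == "mean_o90_w4"


class TestLesionVector:
    def test_zero_margin_makes_all_rim_features_zero(self, planted_phantom):
        vol, mask = planted_phantom
        regions = rr.LesionRegions(tumor=mask, dilated=mask,
                                   rim=rr.VOIMask(np.zeros_like(mask.data)),
                                   margin=0.0)
        vec = rr.extract_lesion_features(vol, regions)
        rim = {k: v for k, v in vec.items() if k.startswith("rim_")}
        assert len(rim) == 100
        assert all(v == 0.0 for v in rim.values())

    def test_vector_has_100_plus_100_manifest_ids(self, planted_phantom):
        vol, mask = planted_phantom
        regions = rr.make_regions(mask, 3.0)
        vec = rr.extract_lesion_features(vol, regions)
        intra = [k for k in vec if k.startswith("intratumoral_")]
        rim = [k for k in vec if k.startswith("rim_")]
        assert len(vec) == 200 and len(intra) == 100 and len(rim) == 100
        assert [k[len("intratumoral_"):] for k in intra] == \
            list(ft.FEATURE_MANIFEST)

    def test_rim_difference_identity_exact(self, planted_phantom):
        vol, mask = planted_phantom
        regions = rr.make_regions(mask, 3.0)
        vec = rr.extract_lesion_features(vol, regions)
        tumor_panel = ft.compute_panel(vol, regions.tumor)
        dilated_panel = ft.compute_panel(vol, regions.dilated)
        for name in ft.FEATURE_MANIFEST:
            assert vec[f"rim_{name}"] + tumor_panel[name] == \
                pytest.approx(dilated_panel[name], abs=1e-12)

    def test_intensity_scaling_invariance_of_discretized_texture(
            self, planted_phantom):
        vol, mask = planted_phantom
        regions = rr.make_regions(mask, 3.0)
        v1 = rr.extract_lesion_features(vol, regions)
        doubled = rr.CTVolume(vol.intensities * 2.0, vol.spacing, vol.origin)
        v2 = rr.extract_lesion_features(doubled, regions)
        for fam in ("glcm", "glrlm", "glszm", "ngtdm", "ngldm"):
            for k in (f"intratumoral_{fam}_{n}"
                      for n in ft._FAMILY_NAMES[fam]):
                assert v2[k] == pytest.approx(v1[k], rel=1e-9), k
        assert v2["intratumoral_firstorder_mean"] == \
            pytest.approx(2 * v1["intratumoral_firstorder_mean"])

    def test_manifest_is_versioned_and_complete(self):
        man = ft.feature_manifest()
        assert man["version"] == ft.MANIFEST_VERSION
        assert man["n_features_per_region"] == 100
        assert sum(len(v) for v in man["families"].values()) == 100
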