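"""Volume I/O, isotropic resampling, and rim-geometry contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rimradiomics as rr
from _oracles import dilate_oracle, lattice_ball_count


def _sphere_mask(radius, spacing, pad_mm=3.0):
    half = int(np.ceil((radius + pad_mm) / min(spacing)))
    ax = [np.arange(-half, half + 1) * s for s in spacing]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    return (xx**2 + yy**2 + zz**2 <= radius**2).astype(np.uint8)


class TestNiftiRoundTrip:
    def test_volume_round_trip_preserves_data_and_spacing(self, tmp_path, rng):
        vol = rr.CTVolume(rng.normal(40, 10, (10, 10, 10)).astype(np.float32),
                          (1.0, 1.0, 1.0), (5.0, -3.0, 0.0))
        path = tmp_path / "v.nii.gz"
        rr.write_volume(vol, path)
        back = rr.read_volume(path)
        np.testing.assert_array_equal(back.intensities,
                                      vol.intensities.astype(np.float32))
        assert back.spacing == vol.spacing
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_binary_mask_survives_round_trip_exactly(self, tmp_path, rng):
        mask = rr.VOIMask((rng.random((8, 8, 8)) > 0.5).astype(np.uint8))
        path = tmp_path / "m.nii.gz"
        from rimradiomics.imaging import write_mask
        write_mask(mask, path)
        back = rr.read_mask(path)
        np.testing.assert_array_equal(back.data, mask.data)

    def test_anisotropic_spacing_preserved_in_header(self, tmp_path):
        vol = rr.CTVolume(np.zeros((4, 4, 4)), (0.7, 0.7, 5.0))
        path = tmp_path / "a.nii.gz"
        rr.write_volume(vol, path)
        assert rr.read_volume(path).spacing == pytest.approx((0.7, 0.7, 5.0))

    def test_4d_data_rejected(self, tmp_path):
        import nibabel as nib
        path = tmp_path / "4d.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4)), path)
        with pytest.raises(rr.ValidationError):
            rr.read_volume(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            rr.read_volume(tmp_path / "nope.nii.gz")


class TestResample:
    def test_isotropic_input_passes_through(self, rng):
        vol = rr.CTVolume(rng.normal(size=(12, 12, 12)))
        mask = rr.VOIMask(np.ones((12, 12, 12), dtype=np.uint8))
        out_v, out_m = rr.resample_isotropic(vol, mask, 1.0)
        np.testing.assert_allclose(out_v.intensities, vol.intensities)
        np.testing.assert_array_equal(out_m.data, mask.data)

    def test_sphere_volume_preserved_under_anisotropic_resampling(self):
        spacing = (0.5, 0.5, 2.0)
        mask_data = _sphere_mask(10.0, spacing)
        vol = rr.CTVolume(np.zeros(mask_data.shape), spacing)
        mask = rr.VOIMask(mask_data, spacing)
        _, out_m = rr.resample_isotropic(vol, mask, 1.0)
        analytic = 4 / 3 * np.pi * 10.0**3     # 4188.8 mm^3
        assert out_m.volume_mm3() == pytest.approx(analytic, rel=0.10)

    def test_constant_volume_stays_constant(self):
        vol = rr.CTVolume(np.full((6, 6, 6), 37.0), (0.8, 0.8, 2.5))
        out_v, _ = rr.resample_isotropic(vol, None, 1.0)
        np.testing.assert_allclose(out_v.intensities, 37.0)
        assert out_v.spacing == (1.0, 1.0, 1.0)

    def test_nonpositive_target_rejected(self):
        vol = rr.CTVolume(np.zeros((4, 4, 4)))
        with pytest.raises(rr.ValidationError):
            rr.resample_isotropic(vol, None, 0.0)

    def test_physical_extent_covered(self):
        vol = rr.CTVolume(np.zeros((10, 10, 4)), (0.7, 0.7, 5.0))
        out_v, _ = rr.resample_isotropic(vol, None, 1.0)
        assert out_v.shape == (7, 7, 20)


class TestDilation:
    def test_single_voxel_3mm_ball_is_123_voxels(self):
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        out = rr.dilate_mask(rr.VOIMask(mask), 3.0)
        assert out.count() == lattice_ball_count(3.0) == 123

    def test_zero_margin_is_identity(self, rng):
        from conftest import random_blob_mask
        mask = rr.VOIMask(random_blob_mask(rng))
        out = rr.dilate_mask(mask, 0.0)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_matches_bruteforce_on_random_blob(self, rng):
        from conftest import random_blob_mask
        mask = random_blob_mask(rng, shape=(16, 16, 16), r=3.0)
        out = rr.dilate_mask(rr.VOIMask(mask), 3.0)
        np.testing.assert_array_equal(out.data, dilate_oracle(mask, 3.0))

    def test_respects_anisotropic_spacing(self):
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        out = rr.dilate_mask(rr.VOIMask(mask, spacing=(1.0, 1.0, 2.0)), 3.0)
        assert out.count() == lattice_ball_count(3.0, (1.0, 1.0, 2.0))
        # 2 mm slices: reaches only +-1 slice out of plane
        assert out.data[:, :, 2].sum() == 0

    def test_added_voxels_within_margin_and_beyond_2mm_exists(self, rng):
        from conftest import random_blob_mask
        from scipy import ndimage
        mask = random_blob_mask(rng, shape=(20, 20, 20), r=3.5)
        out = rr.dilate_mask(rr.VOIMask(mask), 3.0)
        dist = ndimage.distance_transform_edt(mask == 0)
        added = (out.data > 0) & (mask == 0)
        assert dist[added].max() <= 3.0 + 1e-9
        assert dist[added].max() > 2.0

    def test_monotone_and_compositional(self, rng):
        from conftest import random_blob_mask
        mask = rr.VOIMask(random_blob_mask(rng, shape=(20, 20, 20), r=3.0))
        d1 = rr.dilate_mask(mask, 1.0)
        d2 = rr.dilate_mask(mask, 2.0)
        d12 = rr.dilate_mask(d1, 1.0)
        assert np.all(d1.data <= d2.data)            # monotone in margin
        assert np.all(d12.data <= rr.dilate_mask(mask, 2.0).data | d2.data)
        # dilate(m) then dilate(m') is contained in dilate(m+m')
        assert np.all(d12.data <= d2.data)

    def test_negative_margin_and_empty_mask_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=np.uint8)
        mask[2, 2, 2] = 1
        with pytest.raises(rr.ValidationError):
            rr.dilate_mask(rr.VOIMask(mask), -1.0)
        with pytest.raises(rr.EmptyMaskError):
            rr.dilate_mask(rr.VOIMask(np.zeros((5, 5, 5), dtype=np.uint8)), 3.0)


class TestRegions:
    def test_single_voxel_rim_has_122_voxels(self):
        mask = np.zeros((9, 9, 9), dtype=np.uint8)
        mask[4, 4, 4] = 1
        regions = rr.make_regions(rr.VOIMask(mask), 3.0)
        assert regions.rim.count() == 122

    def test_full_grid_tumor_gives_empty_rim_with_warning(self):
        mask = rr.VOIMask(np.ones((5, 5, 5), dtype=np.uint8))
        with pytest.warns(UserWarning, match="rim is empty"):
            regions = rr.make_regions(mask, 3.0)
        assert regions.rim.count() == 0

    @given(st.integers(0, 10_000))
    def test_mask_set_identities_hold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[tuple(rng.integers(2, 8, size=(3, 5)))] = 1
        regions = rr.make_regions(rr.VOIMask(mask), 2.0)
        t, d, r = regions.tumor.data, regions.dilated.data, regions.rim.data
        assert np.all(t <= d)                         # tumor subset of dilated
        np.testing.assert_array_equal(r, d & ~t)      # rim = dilated minus tumor
        assert not np.any(r & t)                      # disjoint
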