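import numpy as np
import pytest
import tifffile

from bonemorph import BinaryVolume, GrayVolume
from bonemorph import _dicom
from bonemorph import synthetic as syn
from bonemorph import volume_io as vio


class TestTiffStack:
    def test_directory_round_trip(self, tmp_path, rng):
        data = rng.integers(0, 4000, size=(10, 64, 64)).astype(np.uint16)
        vol = GrayVolume(data=data, voxel_mm=0.1)
        vio.write_tiff_stack(vol, tmp_path / "stack")
        back = vio.read_tiff_stack(tmp_path / "stack", 0.1)
        assert back.shape == (10, 64, 64)
        assert np.array_equal(back.data, data)
        assert back.data.dtype == np.uint16

    def test_multipage_round_trip(self, tmp_path, rng):
        data = rng.integers(0, 255, size=(5, 16, 16)).astype(np.uint8)
        vol = GrayVolume(data=data, voxel_mm=0.02)
        vio.write_tiff_stack(vol, tmp_path / "vol.tif", multipage=True)
        back = vio.read_tiff_stack(tmp_path / "vol.tif", 0.02)
        assert np.array_equal(back.data, data)

    def test_natural_numeric_ordering(self, tmp_path):
        # s2 must sort before s10 despite lexicographic order
        tifffile.imwrite(tmp_path / "s2.tif", np.full((4, 4), 2, np.uint8))
        tifffile.imwrite(tmp_path / "s10.tif", np.full((4, 4), 10, np.uint8))
        tifffile.imwrite(tmp_path / "s1.tif", np.full((4, 4), 1, np.uint8))
        back = vio.read_tiff_stack(tmp_path, 0.1)
        assert list(back.data[:, 0, 0]) == [1, 2, 10]

    def test_mixed_shapes_error(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((4, 4), np.uint8))
        tifffile.imwrite(tmp_path / "b.tif", np.zeros((5, 4), np.uint8))
        with pytest.raises(ValueError, match="mixed"):
            vio.read_tiff_stack(tmp_path, 0.1)

    def test_empty_directory_error(self, tmp_path):
        with pytest.raises(ValueError, match="no TIFF"):
            vio.read_tiff_stack(tmp_path, 0.1)

    def test_binary_mask_written_as_0_255(self, tmp_path):
        mask = BinaryVolume(mask=np.eye(4, dtype=bool)[None], voxel_mm=0.1)
        vio.write_tiff_stack(mask, tmp_path / "mask")
        back = vio.read_tiff_stack(tmp_path / "mask", 0.1)
        assert set(np.unique(back.data)) == {0, 255}


class TestDicomSeries:
    def test_round_trip(self, tmp_path, rng):
        data = rng.integers(0, 1000, size=(6, 12, 12)).astype(np.float32)
        vol = GrayVolume(data=data, voxel_mm=0.1, modality="cbct")
        vio.write_dicom_series(vol, tmp_path / "series")
        back = vio.read_dicom_series(tmp_path / "series")
        assert back.voxel_mm == pytest.approx(0.1)
        assert np.array_equal(back.data, data)

    def test_shuffled_file_order_sorted_by_position(self, tmp_path, rng):
        data = rng.integers(0, 1000, size=(5, 8, 8)).astype(np.float32)
        vol = GrayVolume(data=data, voxel_mm=0.1, modality="cbct")
        files = vio.write_dicom_series(vol, tmp_path / "series")
        # scramble names so filename order disagrees with position order
        names = ["zz.dcm", "aa.dcm", "mm.dcm", "bb.dcm", "kk.dcm"]
        for f, new in zip(files, names):
            f.rename(f.parent / new)
        back = vio.read_dicom_series(tmp_path / "series")
        assert np.array_equal(back.data, data)

    def test_anisotropic_slice_step_errors(self, tmp_path, rng):
        for z in range(4):
            _dicom.write_dicom_file(
                tmp_path / f"s{z}.dcm",
                rng.integers(0, 100, size=(8, 8)),
                pixel_spacing_mm=0.1, slice_thickness_mm=0.3,
                position_mm=(0, 0, z * 0.3),  # step 0.3 vs in-plane 0.1
                instance_number=z + 1, series_uid="2.25.9.1",
                study_uid="2.25.9", sop_uid=f"2.25.9.1.{z + 1}")
        with pytest.raises(ValueError, match="anisotropic"):
            vio.read_dicom_series(tmp_path)

    def test_missing_spacing_tag_errors(self, tmp_path):
        # hand-built file without PixelSpacing
        body = b"".join([
            _dicom._element(0x0020, 0x000E, b"UI", "2.25.1.1"),
            _dicom._element(0x0020, 0x0032, b"DS", (0, 0, 0)),
            _dicom._element(0x0028, 0x0010, b"US", 2),
            _dicom._element(0x0028, 0x0011, b"US", 2),
            _dicom._element(0x7FE0, 0x0010, b"OW", b"\x00" * 8),
        ])
        (tmp_path / "bad.dcm").write_bytes(b"\x00" * 128 + b"DICM" + body)
        with pytest.raises(ValueError, match="PixelSpacing"):
            vio.read_dicom_series(tmp_path)

    def test_rescale_applied(self, tmp_path):
        _dicom.write_dicom_file(
            tmp_path / "s0.dcm", np.full((4, 4), 10),
            pixel_spacing_mm=0.1, slice_thickness_mm=0.1, position_mm=(0, 0, 0),
            instance_number=1, series_uid="2.25.2.1", study_uid="2.25.2",
            sop_uid="2.25.2.1.1", rescale_slope=2.0, rescale_intercept=-5.0)
        back = vio.read_dicom_series(tmp_path)
        assert np.all(back.data == 15.0)


class TestAnchor:
    @pytest.fixture
    def ball_volume(self, small_phantom):
        _, gray, _ = small_phantom
        padded = syn.pad_top(gray, 0.6, 0.0)
        return syn.embed_anchor_ball(padded, 0.2, 255.0, surface_z=30)

    def test_no_ball_errors(self, small_phantom):
        _, gray, _ = small_phantom
        with pytest.raises(ValueError, match="candidate"):
            vio.locate_anchor(syn.pad_top(gray, 0.6, 0.0))

    def test_two_balls_error(self, small_phantom):
        _, gray, _ = small_phantom
        padded = syn.pad_top(gray, 0.6, 0.0)
        one = syn.embed_anchor_ball(padded, 0.15, 255.0, surface_z=30)
        data = one.data.copy()
        # second bright ball rendered off-axis in the headroom
        z, y, x = np.ogrid[:data.shape[0], :data.shape[1], :data.shape[2]]
        data[(z - 10) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 49] = 255.0
        with pytest.raises(ValueError, match="candidates"):
            vio.locate_anchor(one.with_data(data))

    def test_centroid_and_surface(self, ball_volume):
        loc = vio.locate_anchor(ball_volume)
        expected = syn.anchor_ball_center(ball_volume.shape, 0.2,
                                          ball_volume.voxel_mm, 30)
        assert np.allclose(loc.centroid_voxel, expected, atol=1.0)
        assert abs(loc.top_surface_z - 30) <= 1


class TestRoi:
    @pytest.mark.parametrize("voxel,expected", [
        (0.1, (100, 40, 40)),    # the 4 x 4 x 10 mm cuboid at CBCT resolution
        (0.02, (500, 200, 200)),  # same cuboid at micro resolution
    ])
    def test_grid_shape(self, voxel, expected):
        assert vio.RoiSpec().grid_shape(voxel) == expected

    def test_extract_dims_and_voxel(self, rng):
        vol = GrayVolume(data=rng.random((120, 60, 60)), voxel_mm=0.1)
        anchor = vio.AnchorLocation(centroid_voxel=(5.0, 30.0, 30.0),
                                    top_surface_z=10)
        roi = vio.RoiSpec(extent_mm=(4.0, 4.0, 10.0))
        out = vio.extract_roi(vol, anchor, roi)
        assert out.shape == (100, 40, 40)
        assert out.voxel_mm == vol.voxel_mm

    def test_identity_crop(self, rng):
        vol = GrayVolume(data=rng.random((10, 8, 8)), voxel_mm=0.5)
        roi = vio.RoiSpec(extent_mm=(4.0, 4.0, 5.0), anchor_mode="volume_center")
        out = vio.extract_roi(vol, None, roi)
        assert np.array_equal(out.data, vol.data)

    def test_out_of_bounds_errors(self, rng):
        vol = GrayVolume(data=rng.random((20, 20, 20)), voxel_mm=0.1)
        anchor = vio.AnchorLocation(centroid_voxel=(0.0, 10.0, 10.0),
                                    top_surface_z=5)
        with pytest.raises(ValueError, match="exceeds"):
            vio.extract_roi(vol, anchor, vio.RoiSpec(extent_mm=(1.0, 1.0, 5.0)))

    def test_binary_volume_crop(self):
        mask = BinaryVolume(mask=np.ones((10, 10, 10), bool), voxel_mm=0.1,
                            provenance="truth")
        roi = vio.RoiSpec(extent_mm=(0.5, 0.5, 0.5), anchor_mode="volume_center")
        out = vio.extract_roi(mask, None, roi)
        assert isinstance(out, BinaryVolume)
        assert out.shape == (5, 5, 5)
        assert out.provenance == "truth"

    def test_physical_size_within_one_voxel(self):
        spec = vio.RoiSpec(extent_mm=(3.7, 4.2, 9.9))
        for voxel in (0.02, 0.1, 0.25):
            nz, ny, nx = spec.grid_shape(voxel)
            for n, ext in zip((nx, ny, nz), spec.extent_mm):
                assert abs(n * voxel - ext) < voxel


class TestMatchedRois:
    def test_micro_and_cbct_cover_same_region(self):
        """Ground-truth BV/TV over the micro-anchored and CBCT-anchored
        crops agrees within 2 percentage points."""
        phantom = syn.PhantomSpec(shape_mm=(1.6, 1.6, 2.8), target_bvtv=0.3,
                                  feature_sigma_mm=0.08, voxel_mm=0.02, seed=21)
        cohort = syn.generate_cohort(
            3, seed=21, bvtv_range=(0.15, 0.35), phantom=phantom,
            degradation=syn.DegradationSpec(psf_sigma_mm=0.1, noise_sigma=2.0,
                                            axial_shading_amplitude=0.15),
            anchor_radius_mm=0.3, headroom_mm=0.8)
        roi = vio.RoiSpec(extent_mm=(1.0, 1.0, 2.0))
        for sp in cohort:
            micro_loc = vio.locate_anchor(sp.micro)
            truth_micro = vio.extract_roi(sp.truth, micro_loc, roi)
            cbct_loc = vio.locate_anchor(sp.cbct)
            # map the CBCT ROI into micro coordinates (factor 5)
            nz, ny, nx = roi.grid_shape(sp.cbct.voxel_mm)
            _, cy, cx = cbct_loc.centroid_voxel
            oz = cbct_loc.top_surface_z * 5
            oy = (round(cy) - ny // 2) * 5
            ox = (round(cx) - nx // 2) * 5
            truth_cbct = sp.truth.mask[oz:oz + nz * 5, oy:oy + ny * 5,
                                       ox:ox + nx * 5]
            a = 100.0 * truth_micro.mask.mean()
            b = 100.0 * truth_cbct.mean()
            assert abs(a - b) < 2.0


class TestTopSurface:
    def test_padded_phantom_surface(self, small_phantom):
        _, gray, _ = small_phantom
        padded = syn.pad_top(gray, 0.6, 0.0)
        assert abs(vio.find_top_surface(padded) - 30) <= 1

    def test_flat_volume_errors(self):
        v = GrayVolume(data=np.full((6, 4, 4), 9.0), voxel_mm=0.1)
        with pytest.raises(ValueError, match="surface"):
            vio.find_top_surface(v)
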