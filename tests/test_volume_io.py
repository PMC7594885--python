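"""Volume model, MetaImage round-trips, cube packing and the head phantom."""
import numpy as np
import pytest

from isodrr import (DEFAULT_LANDMARKS_MM, HeadPhantomParams, LandmarkCatalogue,
                    MalformedHeaderError, TruncatedVolumeError,
                    UnsupportedElementTypeError, VoxelVolume, default_catalogue,
                    generate_head_phantom, pack_to_cube, phantom_code_at,
                    read_volume, write_volume)


def _random_volume(rng, shape=(16, 16, 16), dtype=np.uint8, spacing=(0.5, 0.6, 0.7)):
    high = np.iinfo(dtype).max
    return VoxelVolume(rng.integers(0, high + 1, size=shape).astype(dtype),
                       spacing=spacing, origin=(1.0, -2.0, 3.0))


class TestMetaImageIO:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        vol = _random_volume(rng)
        read_back = read_volume(write_volume(vol, tmp_path / "v.mhd"))
        np.testing.assert_array_equal(read_back.intensities, vol.intensities)
        assert read_back.spacing == vol.spacing
        assert read_back.origin == vol.origin

    def test_16bit_volume_preserves_ct_spacing(self, tmp_path, rng):
        vol = _random_volume(rng, shape=(8, 12, 12), dtype=np.uint16,
                             spacing=(0.46, 0.46, 1.0))
        read_back = read_volume(write_volume(vol, tmp_path / "ct.mhd"))
        assert read_back.spacing == (0.46, 0.46, 1.0)
        assert read_back.intensities.dtype == np.uint16

    def test_truncated_raw_payload_is_distinct_error(self, tmp_path, rng):
        path = write_volume(_random_volume(rng), tmp_path / "v.mhd")
        raw = tmp_path / "v.raw"
        raw.write_bytes(raw.read_bytes()[:-64])
        with pytest.raises(TruncatedVolumeError, match="bytes"):
            read_volume(path)

    def test_malformed_header_is_distinct_error(self, tmp_path):
        bad = tmp_path / "bad.mhd"
        bad.write_text("ObjectType = Image\nNDims = 3\nthis line has no equals sign\n")
        with pytest.raises(MalformedHeaderError):
            read_volume(bad)

    def test_unsupported_element_type_is_distinct_error(self, tmp_path, rng):
        path = write_volume(_random_volume(rng), tmp_path / "v.mhd")
        text = path.read_text().replace("MET_UCHAR", "MET_FLOAT")
        path.write_text(text)
        with pytest.raises(UnsupportedElementTypeError, match="MET_FLOAT"):
            read_volume(path)

    def test_missing_header_key_is_malformed(self, tmp_path, rng):
        path = write_volume(_random_volume(rng), tmp_path / "v.mhd")
        text = "\n".join(l for l in path.read_text().splitlines()
                         if not l.startswith("DimSize"))
        path.write_text(text)
        with pytest.raises(MalformedHeaderError, match="DimSize"):
            read_volume(path)


class TestVoxelVolume:
    def test_rejects_non_positive_spacing(self, rng):
        with pytest.raises(ValueError, match="spacing"):
            VoxelVolume(rng.integers(0, 2, (4, 4, 4)).astype(np.uint8),
                        spacing=(1.0, 0.0, 1.0))

    def test_rejects_left_handed_axes(self, rng):
        with pytest.raises(ValueError, match="right-handed"):
            VoxelVolume(rng.integers(0, 2, (4, 4, 4)).astype(np.uint8),
                        spacing=(1, 1, 1), axes="RAS")

    def test_extent_is_count_times_spacing(self, rng):
        vol = _random_volume(rng, shape=(8, 10, 12), spacing=(0.5, 1.0, 2.0))
        assert vol.extent_mm == (4.0, 10.0, 24.0)


class TestPackToCube:
    def test_ct_acquisition_spacing_arithmetic(self):
        # 184 slices of 512 x 512 at (1.0, 0.46, 0.46) mm: the packed cube
        # must keep the physical extent, so spacing = extent / 256 per axis
        vol = VoxelVolume(
            np.tile(np.arange(512, dtype=np.uint16), (184, 512, 1)),
            spacing=(1.0, 0.46, 0.46),
        )
        packed = pack_to_cube(vol)
        assert packed.shape == (256, 256, 256)
        assert packed.intensities.dtype == np.uint8
        np.testing.assert_allclose(packed.spacing, (0.71875, 0.92, 0.92))
        np.testing.assert_allclose(packed.extent_mm, vol.extent_mm)

    def test_identity_on_full_range_cube(self, rng):
        arr = rng.integers(0, 256, size=(256, 256, 256)).astype(np.uint8)
        arr.flat[0], arr.flat[1] = 0, 255
        vol = VoxelVolume(arr, spacing=(1.0, 1.0, 1.0))
        packed = pack_to_cube(vol)
        np.testing.assert_array_equal(packed.intensities, arr)
        assert packed.spacing == vol.spacing

    def test_idempotent_on_packed_volumes(self, head_phantom):
        vol, _ = head_phantom
        repacked = pack_to_cube(vol)
        np.testing.assert_array_equal(repacked.intensities, vol.intensities)

    def test_constant_input_maps_to_zero(self):
        vol = VoxelVolume(np.full((10, 10, 10), 77, dtype=np.uint8), spacing=(1, 1, 1))
        packed = pack_to_cube(vol)
        assert packed.intensities.max() == 0

    def test_extent_preserved_for_anisotropic_input(self, rng):
        vol = _random_volume(rng, shape=(20, 30, 40), spacing=(0.3, 0.7, 1.1))
        np.testing.assert_allclose(pack_to_cube(vol).extent_mm, vol.extent_mm)


class TestHeadPhantom:
    def test_midline_landmarks_sit_on_msp(self, head_phantom):
        _, cat = head_phantom
        for name in ("Sella", "ANS", "Bregma", "Glabella", "Nasion", "Petrous",
                     "External Occipital Protuberance"):
            assert cat.get(name)[0] == 0.0

    def test_paired_landmarks_mirror_about_msp(self, head_phantom):
        _, cat = head_phantom
        for left, right in (("Lt EAM", "Rt EAM"), ("Lt TMJ", "Rt TMJ"),
                            ("Lt Outer Canthus", "Rt Outer Canthus")):
            l, r = cat.get(left), cat.get(right)
            np.testing.assert_allclose(l * np.array([-1, 1, 1]), r)

    def test_marker_centre_voxel_carries_marker_code(self, head_phantom):
        vol, cat = head_phantom
        params = HeadPhantomParams()
        for name in ("Sella", "Bregma", "Rt EAM"):
            idx = np.rint(vol.world_to_index(cat.get(name))).astype(int)
            expected = phantom_code_at(cat.get(name), params, cat)[0]
            assert vol.intensities[tuple(idx)] == expected == 255

    def test_voxelization_matches_analytic_model_away_from_surfaces(
            self, head_phantom, rng):
        vol, cat = head_phantom
        params = HeadPhantomParams()
        idx = rng.integers(1, 255, size=(150_000, 3))
        centres = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
        analytic = phantom_code_at(centres, params, cat)
        voxel = vol.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
        # keep only voxels whose 6-neighbourhood is analytically uniform
        # (i.e. more than one voxel from any material surface)
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        uniform = np.ones(len(idx), dtype=bool)
        for off in offsets:
            shifted = centres + off * np.asarray(vol.spacing)
            uniform &= phantom_code_at(shifted, params, cat) == analytic
        agreement = (voxel[uniform] == analytic[uniform]).mean()
        assert agreement >= 0.999

    def test_marker_outside_volume_names_landmark(self):
        cat = LandmarkCatalogue({**DEFAULT_LANDMARKS_MM, "Escapee": (0.0, 0.0, 130.0)})
        with pytest.raises(ValueError, match="Escapee"):
            generate_head_phantom(catalogue=cat)

    def test_overlapping_markers_name_landmarks(self):
        cat = LandmarkCatalogue({**DEFAULT_LANDMARKS_MM, "Shadow": (0.0, 12.5, 18.5)})
        with pytest.raises(ValueError, match="Shadow"):
            generate_head_phantom(catalogue=cat)

    def test_catalogue_csv_round_trip(self, tmp_path):
        cat = default_catalogue()
        cat2 = LandmarkCatalogue.from_csv(cat.to_csv(tmp_path / "lm.csv"))
        assert cat2.names == cat.names
        for name in cat.names:
            np.testing.assert_allclose(cat2.get(name), cat.get(name))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkCatalogue([*default_catalogue(), *default_catalogue()])
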