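"""Containers, file round trips and resampling primitives."""

import numpy as np
import pytest
import SimpleITK as sitk

from bresym import volumes_io as vio


@pytest.fixture()
def volume(rng):
    return vio.ImageVolume(
        data=rng.standard_normal((4, 5, 6)).astype(np.float32),
        spacing=(1.0, 1.25, 2.0),
        origin=(-3.0, 0.0, 7.5),
    )


class TestContainers:
    def test_invalid_spacing_rejected(self):
        with pytest.raises(vio.GeometryError):
            vio.ImageVolume(np.zeros((3, 3, 3)), spacing=(1, 0, 1))

    def test_non_3d_rejected(self):
        with pytest.raises(vio.DimensionalityError):
            vio.ImageVolume(np.zeros((3, 3)))

    def test_world_index_round_trip(self, volume, rng):
        pts = rng.uniform(-5, 5, size=(10, 3))
        assert np.allclose(volume.index_to_world(volume.world_to_index(pts)), pts)

    def test_label_codes_restricted(self):
        with pytest.raises(ValueError):
            vio.LabelVolume(np.full((3, 3, 3), 7, dtype=np.int16))

    def test_rigid_requires_rotation(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError):
            vio.RigidTransform(bad)

    def test_landmarks_require_unique_finite(self):
        with pytest.raises(ValueError):
            vio.LandmarkSet([1, 1], [[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError):
            vio.LandmarkSet([1, 2], [[0, 0, 0], [np.inf, 1, 1]])


class TestFileIO:
    @pytest.mark.parametrize("ext", ["nii.gz", "nii", "mha"])
    def test_round_trip_preserves_data_and_geometry(self, volume, tmp_path, ext):
        path = str(tmp_path / f"vol.{ext}")
        vio.write_volume(volume, path)
        back = vio.read_volume(path)
        assert back.data.dtype == volume.data.dtype
        assert np.array_equal(back.data, volume.data)
        assert np.allclose(back.spacing, volume.spacing)
        assert np.allclose(back.origin, volume.origin)
        assert np.allclose(back.orientation, volume.orientation)

    def test_unsupported_format_rejected(self, volume, tmp_path):
        with pytest.raises(vio.VolumeFormatError):
            vio.write_volume(volume, str(tmp_path / "vol.png"))
        with pytest.raises(vio.VolumeFormatError):
            vio.read_volume(str(tmp_path / "missing.nii"))

    def test_2d_payload_rejected(self, tmp_path):
        path = str(tmp_path / "flat.nii.gz")
        sitk.WriteImage(sitk.GetImageFromArray(np.zeros((6, 5), np.float32)), path)
        with pytest.raises(vio.DimensionalityError):
            vio.read_volume(path)

    def test_landmark_csv_round_trip(self, tmp_path, rng):
        lm = vio.LandmarkSet(np.arange(5), rng.uniform(-10, 10, (5, 3)))
        path = str(tmp_path / "lm.csv")
        vio.write_landmarks(lm, path)
        back = vio.read_landmarks(path)
        assert np.array_equal(back.labels, lm.labels)
        assert np.allclose(back.points, lm.points)

    def test_rigid_round_trip(self, tmp_path):
        from scipy.spatial.transform import Rotation

        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        m[:3, 3] = [1.5, -2.0, 3.0]
        t = vio.RigidTransform(m)
        path = str(tmp_path / "rigid.txt")
        vio.write_rigid(t, path)
        assert np.allclose(vio.read_rigid(path).matrix, m)


class TestPullbackResample:
    def test_zero_dvf_is_identity(self, volume):
        dvf = np.zeros((3, *volume.shape))
        out = vio.pullback_resample(volume, dvf)
        assert np.allclose(out.data, volume.data)

    def test_constant_dvf_on_constant_volume(self, volume):
        const = volume.with_data(np.full(volume.shape, 4.2))
        dvf = np.zeros((3, *volume.shape))
        dvf[1] = 0.6  # within the domain for interior voxels
        out = vio.pullback_resample(const, dvf, pad_value=4.2)
        assert np.allclose(out.data, 4.2)

    def test_one_voxel_shift_samples_neighbour(self):
        vol = vio.ImageVolume(
            np.indices((6, 6, 6), dtype=float)[0], spacing=(2.0, 2.0, 2.0)
        )
        dvf = np.zeros((3, 6, 6, 6))
        dvf[0] = 2.0  # +1 voxel along axis 0, in mm
        out = vio.pullback_resample(vol, dvf)
        interior = (slice(0, -1), slice(None), slice(None))
        assert np.allclose(out.data[interior], vol.data[interior] + 1)

    def test_nearest_never_invents_label_codes(self, rng):
        labels = rng.integers(0, 4, (7, 7, 7)).astype(np.int16)
        vol = vio.ImageVolume(labels, spacing=(1, 1, 1))
        dvf = 1.7 * rng.standard_normal((3, 7, 7, 7))
        out = vio.pullback_resample(vol, dvf, "nearest", pad_value=0)
        assert set(np.unique(out.data)) <= set(np.unique(labels)) | {0}

    def test_grid_mismatch_rejected(self, volume):
        with pytest.raises(vio.GeometryError):
            vio.pullback_resample(volume, np.zeros((3, 2, 2, 2)))


class TestDisplacementInversion:
    def test_inverts_smooth_forward_field(self):
        shape = (12, 12, 12)
        spacing = (2.0, 2.0, 2.0)
        idx = np.indices(shape, dtype=float) * 2.0
        fwd = np.zeros((3, *shape))
        fwd[0] = 1.5 * np.sin(idx[1] / 8.0)  # smooth, |grad| < 1
        inv = vio.invert_displacement_field(fwd, spacing)
        # composition ~ identity away from the border
        sl = (slice(2, -2),) * 3
        comp = fwd[0][sl] + inv[0][sl]  # x-displacement of round trip at fixed y
        assert np.abs(comp).max() < 0.05


class TestIntensityInversion:
    def test_endpoints_swap(self):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = 100.0
        vol = vio.ImageVolume(data, (1, 1, 1))
        mask = np.ones((3, 3, 3), bool)
        out = vio.intensity_inversion(vol, mask, 0.0, 100.0)
        assert out.data[0, 0, 0] == pytest.approx(0.0)
        assert out.data[1, 1, 1] == pytest.approx(100.0)

    def test_midpoint_maps_to_midpoint(self):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = 100.0
        data[2, 2, 2] = 50.0
        vol = vio.ImageVolume(data, (1, 1, 1))
        out = vio.intensity_inversion(vol, np.ones((3, 3, 3), bool), 0.0, 100.0)
        assert out.data[2, 2, 2] == pytest.approx(50.0)

    def test_involution_inside_mask(self, rng):
        data = rng.uniform(10, 200, (4, 4, 4))
        vol = vio.ImageVolume(data, (1, 1, 1))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        lo, hi = data[mask].min(), data[mask].max()
        once = vio.intensity_inversion(vol, mask, lo, hi)
        twice = vio.intensity_inversion(once, mask, lo, hi)
        assert np.allclose(twice.data[mask], data[mask])

    def test_degenerate_range_rejected(self):
        vol = vio.ImageVolume(np.ones((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError):
            vio.intensity_inversion(vol, np.ones((3, 3, 3), bool))


class TestApplyRigid:
    def test_identity_is_noop(self, volume):
        out = vio.apply_rigid(volume, vio.RigidTransform.identity())
        assert np.allclose(out.data, volume.data)

    def test_translation_equals_constant_dvf_pullback(self, volume):
        m = np.eye(4)
        m[:3, 3] = [1.0, 0.0, 0.0]
        by_rigid = vio.apply_rigid(volume, vio.RigidTransform(m))
        dvf = np.zeros((3, *volume.shape))
        dvf[0] = 1.0
        by_dvf = vio.pullback_resample(volume, dvf)
        assert np.allclose(by_rigid.data, by_dvf.data)

    def test_four_quarter_turns_restore_volume(self, rng):
        from scipy.spatial.transform import Rotation

        data = rng.standard_normal((7, 7, 7))
        # rotate about the grid centre so the domain maps onto itself
        vol = vio.ImageVolume(data, (1, 1, 1), origin=(-3, -3, -3))
        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = vio.RigidTransform(m)
        out = vol
        for _ in range(4):
            out = vio.apply_rigid(out, t, "nearest")
        assert np.allclose(out.data, data)
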