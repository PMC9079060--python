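import numpy as np
import pytest
import SimpleITK as sitk

from sinuseg.errors import FormatError, GeometryError, ShapeError
from sinuseg.volume_io import (
    BinaryMask,
    SurfaceMesh,
    Volume,
    read_mask,
    read_stl,
    read_volume,
    resample_isotropic,
    resample_to_shape,
    write_dicom_series,
    write_mask,
    write_nifti,
    write_stl,
)

UNIT_CUBE_VERTS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
    dtype=float,
)
UNIT_CUBE_FACES = np.array(
    [
        [0, 2, 1], [1, 2, 3],  # z=0
        [4, 5, 6], [5, 7, 6],  # z=1
        [0, 1, 4], [1, 5, 4],  # y=0
        [2, 6, 3], [3, 6, 7],  # y=1
        [0, 4, 2], [2, 4, 6],  # x=0
        [1, 3, 5], [3, 7, 5],  # x=1
    ]
)


class TestVolumeTypes:
    def test_volume_invariants(self):
        with pytest.raises(GeometryError):
            Volume(np.zeros((4, 4, 4)), (0.0, 1.0, 1.0))
        with pytest.raises(ShapeError):
            Volume(np.zeros((4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ShapeError):
            Volume(np.full((2, 2, 2), np.nan), (1.0, 1.0, 1.0))

    def test_mask_values_strictly_binary(self):
        with pytest.raises(ShapeError):
            BinaryMask(np.full((2, 2, 2), 2), (1, 1, 1))
        m = BinaryMask(np.ones((2, 2, 2)), (1, 1, 1))
        assert m.voxels.dtype == np.uint8 and m.count() == 8

    def test_mesh_drops_degenerate_faces(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        faces = [[0, 1, 2], [0, 1, 1]]  # second face has zero area
        m = SurfaceMesh(verts, faces)
        assert m.n_faces == 1


class TestNifti:
    def test_round_trip_voxels_exact_geometry_close(self, tmp_path, rng):
        v = Volume(rng.normal(0, 300, (9, 8, 7)).astype(np.float32), (0.5, 0.4, 0.3), (5, 6, 7))
        write_nifti(v, tmp_path / "v.nii.gz")
        r = read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(r.voxels, v.voxels)
        np.testing.assert_allclose(r.spacing, v.spacing, rtol=1e-6)
        np.testing.assert_allclose(r.origin, v.origin, atol=1e-5)

    def test_mask_round_trip(self, tmp_path, rng):
        m = BinaryMask((rng.uniform(size=(6, 6, 6)) < 0.5).astype(np.uint8), (1, 1, 1))
        write_mask(m, tmp_path / "m.nii.gz")
        np.testing.assert_array_equal(read_mask(tmp_path / "m.nii.gz").voxels, m.voxels)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")


class TestDicom:
    def test_series_metadata_and_order(self, tmp_path, rng):
        v = Volume(rng.normal(40, 100, (20, 10, 8)).round(), (0.45, 0.3, 0.3), (0, 0, 0))
        write_dicom_series(v, tmp_path / "dcm")
        r = read_volume(tmp_path / "dcm", format="dicom_dir")
        assert r.shape == (20, 10, 8)
        np.testing.assert_allclose(r.spacing, (0.45, 0.3, 0.3), rtol=1e-6)
        np.testing.assert_array_equal(r.voxels, v.voxels)

    def test_rotated_slice_rejected(self, tmp_path, rng):
        v = Volume(rng.normal(0, 10, (5, 6, 6)).round(), (0.5, 0.5, 0.5))
        paths = write_dicom_series(v, tmp_path / "dcm")
        img = sitk.ReadImage(str(paths[2]))
        img.SetMetaData("0020|0037", "0\\1\\0\\1\\0\\0")
        w = sitk.ImageFileWriter()
        w.KeepOriginalImageUIDOn()
        w.SetFileName(str(paths[2]))
        w.Execute(img)
        with pytest.raises(FormatError, match="0020,0037"):
            read_volume(tmp_path / "dcm")


class TestResampling:
    def test_identity_when_already_isotropic(self, rng):
        v = Volume(rng.normal(size=(8, 8, 8)).astype(np.float32), (0.4, 0.4, 0.4))
        r = resample_isotropic(v, 0.4)
        np.testing.assert_array_equal(r.voxels, v.voxels)

    def test_shape_arithmetic(self):
        v = Volume(np.zeros((64, 64, 64), np.float32), (0.5, 0.5, 0.5))
        assert resample_isotropic(v, 1.0).shape == (32, 32, 32)

    def test_constant_stays_constant(self):
        v = Volume(np.full((16, 16, 16), 123.0, np.float32), (0.5, 0.5, 0.5))
        r = resample_isotropic(v, 0.7)
        np.testing.assert_allclose(r.voxels, 123.0, rtol=1e-6)

    def test_idempotence(self, noisy_phantom):
        r1 = resample_isotropic(noisy_phantom.volume, 0.55)
        r2 = resample_isotropic(r1, 0.55)
        np.testing.assert_array_equal(r1.voxels, r2.voxels)

    def test_extent_preserved_within_one_voxel(self, noisy_phantom):
        v = noisy_phantom.volume
        for t in (0.3, 0.5, 0.9):
            r = resample_isotropic(v, t)
            assert np.all(np.abs(r.physical_extent() - v.physical_extent()) < t)

    def test_mask_stays_binary(self, noiseless_phantom):
        r = resample_isotropic(noiseless_phantom.truth, 0.63)
        assert set(np.unique(r.voxels)) <= {0, 1}

    def test_bad_target(self, noisy_phantom):
        with pytest.raises(ValueError):
            resample_isotropic(noisy_phantom.volume, -1.0)

    def test_resample_to_shape(self, noisy_phantom):
        r = resample_to_shape(noisy_phantom.volume, (32, 32, 32))
        assert r.shape == (32, 32, 32)
        np.testing.assert_allclose(r.physical_extent(), noisy_phantom.volume.physical_extent(), rtol=1e-6)


class TestStl:
    def test_cube_round_trip(self, tmp_path):
        m = SurfaceMesh(UNIT_CUBE_VERTS, UNIT_CUBE_FACES)
        write_stl(m, tmp_path / "c.stl")
        r = read_stl(tmp_path / "c.stl")
        assert r.n_faces == 12
        got = set(map(tuple, np.round(r.vertices, 5)))
        assert got == set(map(tuple, UNIT_CUBE_VERTS))

    def test_binary_ascii_equivalent(self, tmp_path):
        m = SurfaceMesh(UNIT_CUBE_VERTS, UNIT_CUBE_FACES)
        write_stl(m, tmp_path / "b.stl", mode="binary")
        write_stl(m, tmp_path / "a.stl", mode="ascii")
        rb, ra = read_stl(tmp_path / "b.stl"), read_stl(tmp_path / "a.stl")
        assert rb.n_faces == ra.n_faces == 12
        assert np.allclose(sorted(map(tuple, rb.vertices)), sorted(map(tuple, ra.vertices)))

    def test_watertight_surface_survives_round_trip(self, tmp_path, noiseless_phantom):
        from sinuseg.pipeline import PipelineConfig, extract_mesh

        mesh = extract_mesh(noiseless_phantom.truth, PipelineConfig(smoothing_method="none"))
        write_stl(mesh, tmp_path / "s.stl")
        r = read_stl(tmp_path / "s.stl")
        assert r.n_faces == mesh.n_faces
        # every edge shared by exactly two faces
        edges = np.sort(
            np.concatenate([r.faces[:, [0, 1]], r.faces[:, [1, 2]], r.faces[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()

    def test_empty_mesh_rejected(self, tmp_path):
        m = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            write_stl(m, tmp_path / "e.stl")
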