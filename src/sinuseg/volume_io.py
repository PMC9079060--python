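"""Volumetric image containers and I/O.

The pipeline exchanges three kinds of objects:

* :class:`Volume` -- a 3D grid of CT intensities in Hounsfield units (HU)
  with per-axis voxel spacing and a world origin, both in millimetres.
* :class:`BinaryMask` -- a {0,1} grid sharing a Volume's geometry.
* :class:`SurfaceMesh` -- a triangle mesh in mm world coordinates.

Conventions
-----------
Arrays are indexed ``(i, j, k)``; ``spacing`` and ``origin`` are stored in
the same axis order as the array. The centre of voxel ``(i, j, k)`` sits at
``origin + index * spacing``. Volumes read from DICOM are reoriented to a
single right-handed (LPS-closest) axis convention at load time so every
downstream operation can ignore orientation.

File formats go through SimpleITK (DICOM series, NIfTI-1) and trimesh
(STL); nothing here re-implements a parser.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import SimpleITK as sitk
import trimesh

from .errors import FormatError, GeometryError, ShapeError

__all__ = [
    "Volume",
    "BinaryMask",
    "SurfaceMesh",
    "read_volume",
    "write_nifti",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "resample_to_shape",
    "write_stl",
    "read_stl",
]


@dataclass
class Volume:
    """A 3D scalar grid of HU intensities with physical geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ShapeError(f"volume must be 3D with each axis >= 1, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ShapeError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def physical_extent(self) -> np.ndarray:
        """Extent of the voxel grid in mm per axis (shape * spacing)."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A {0,1} segmentation grid sharing a :class:`Volume`'s geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ShapeError(f"mask values must be exactly 0 or 1, found {vals[:5]}")
        self.voxels = arr.astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ShapeError(f"mask must be 3D, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm world coordinates.

    Zero-area faces are dropped at construction so the invariant
    "no degenerate faces" holds for every instance.
    """

    vertices: np.ndarray
    faces: np.ndarray
    open_boundary: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ShapeError("mesh vertex coordinates must be finite")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ShapeError("face indices out of range")
        if len(self.faces):
            a = self.vertices[self.faces[:, 0]]
            areas = 0.5 * np.linalg.norm(
                np.cross(self.vertices[self.faces[:, 1]] - a, self.vertices[self.faces[:, 2]] - a),
                axis=1,
            )
            self.faces = self.faces[areas > 0.0]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def is_watertight(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        if not len(self.faces):
            return False
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> Volume:
    arr = sitk.GetArrayFromImage(img).astype(np.float32)
    # SimpleITK reports spacing/origin in (x, y, z); the array is (z, y, x).
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(arr, spacing, origin)


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels))
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    img.SetOrigin(tuple(reversed([float(o) for o in origin])))
    return img


def _read_dicom_series(path: Path) -> Volume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in ("", ".dcm", ".ima"))
    if not files:
        raise FormatError(f"no DICOM files found in {path}")
    reader = sitk.ImageFileReader()
    reader.LoadPrivateTagsOn()
    orientations: list[tuple[float, ...]] = []
    positions: list[np.ndarray] = []
    spacings: list[tuple[float, ...]] = []
    for f in files:
        reader.SetFileName(str(f))
        reader.ReadImageInformation()
        try:
            iop = tuple(float(v) for v in reader.GetMetaData("0020|0037").split("\\"))
            ipp = np.array([float(v) for v in reader.GetMetaData("0020|0032").split("\\")])
            pxs = tuple(float(v) for v in reader.GetMetaData("0028|0030").split("\\"))
        except RuntimeError as exc:  # missing geometry tags
            raise FormatError(f"{f.name}: missing DICOM geometry tag: {exc}") from exc
        orientations.append(iop)
        positions.append(ipp)
        spacings.append(pxs)
    ref = np.array(orientations[0])
    for f, o in zip(files, orientations):
        if not np.allclose(o, ref, atol=1e-4):
            raise FormatError(
                f"inconsistent DICOM series: ImageOrientationPatient (0020,0037) of "
                f"{f.name} differs from the first slice"
            )
    for f, s in zip(files, spacings):
        if not np.allclose(s, spacings[0], atol=1e-6):
            raise FormatError(
                f"inconsistent DICOM series: PixelSpacing (0028,0030) of {f.name} differs"
            )
    # sort slices along the slice normal
    row, col = ref[:3], ref[3:]
    normal = np.cross(row, col)
    order = np.argsort([float(np.dot(p, normal)) for p in positions])
    series = sitk.ImageSeriesReader()
    series.SetFileNames([str(files[i]) for i in order])
    img = series.Execute()
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D series, got dimension {img.GetDimension()}")
    img = sitk.DICOMOrient(img, "LPS")
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        warnings.warn("oblique DICOM acquisition: residual off-axis direction ignored", stacklevel=2)
    return _from_sitk(img)


def read_volume(path: str | os.PathLike, format: Literal["dicom_dir", "nifti"] | None = None) -> Volume:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    ``format`` is inferred from the path when omitted (directory ->
    ``dicom_dir``, file -> ``nifti``). DICOM slices are sorted by position
    along the slice normal; a series with mixed orientation or in-plane
    spacing raises :class:`FormatError` naming the offending attribute.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if format is None:
        format = "dicom_dir" if p.is_dir() else "nifti"
    if format == "dicom_dir":
        return _read_dicom_series(p)
    if format == "nifti":
        try:
            img = sitk.ReadImage(str(p))
        except RuntimeError as exc:
            raise FormatError(f"cannot read {p}: {exc}") from exc
        return _from_sitk(img)
    raise ValueError(f"unknown format {format!r}")


def write_nifti(v: Volume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a Volume (float32) or BinaryMask (uint8) to a NIfTI-1 file."""
    sitk.WriteImage(_to_sitk(v.voxels, v.spacing, v.origin), str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask from NIfTI; any nonzero voxel becomes 1."""
    v = read_volume(path, format="nifti")
    return BinaryMask((v.voxels > 0.5).astype(np.uint8), v.spacing, v.origin)


def write_mask(m: BinaryMask, path: str | os.PathLike) -> None:
    write_nifti(m, path)


def write_dicom_series(v: Volume, out_dir: str | os.PathLike) -> list[Path]:
    """Write a Volume as a synthetic axial DICOM series (one int16 CT slice
    per file, geometry tags populated). Intended for phantom export and for
    exercising the DICOM reading path; intensities are rounded to integers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, _, _ = v.shape
    dz, dy, dx = v.spacing
    oz, oy, ox = v.origin
    writer = sitk.ImageFileWriter()
    writer.KeepOriginalImageUIDOn()
    paths = []
    for k in range(n):
        sl = sitk.GetImageFromArray(np.round(v.voxels[k]).astype(np.int16))
        sl.SetSpacing((dx, dy))
        for tag, val in {
            "0008|0060": "CT",
            "0020|000e": "1.2.826.0.1.3680043.9999.1",  # shared series UID
            "0020|0013": str(k + 1),
            "0020|0037": "1\\0\\0\\0\\1\\0",
            "0020|0032": f"{ox}\\{oy}\\{oz + k * dz}",
            "0018|0050": f"{dz}",
            "0028|0030": f"{dy}\\{dx}",
        }.items():
            sl.SetMetaData(tag, val)
        p = out / f"slice_{k:04d}.dcm"
        writer.SetFileName(str(p))
        writer.Execute(sl)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def _resample(voxels, spacing, origin, out_shape, out_spacing, interpolation, default):
    img = _to_sitk(voxels, spacing, origin)
    res = sitk.Resample(
        img,
        tuple(int(s) for s in reversed(out_shape)),
        sitk.Transform(),
        _INTERP[interpolation],
        tuple(reversed([float(o) for o in origin])),
        tuple(reversed([float(s) for s in out_spacing])),
        img.GetDirection(),
        float(default),
        sitk.sitkFloat32,
    )
    return sitk.GetArrayFromImage(res)


def resample_isotropic(
    v: Volume | BinaryMask, target_spacing: float, interpolation: str | None = None
) -> Volume | BinaryMask:
    """Resample to isotropic ``target_spacing`` mm voxels.

    Output shape per axis is ``round(shape * spacing / target)`` (min 1), so
    the physical extent is preserved to within one voxel. Intensities are
    interpolated linearly, masks with nearest-neighbour (so they stay
    binary); an explicit ``interpolation`` overrides the default.
    """
    t = float(target_spacing)
    if t <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    is_mask = isinstance(v, BinaryMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if np.allclose(v.spacing, (t, t, t)):
        cls = BinaryMask if is_mask else Volume
        return cls(v.voxels.copy(), (t, t, t), v.origin)
    out_shape = tuple(
        max(1, int(round(n * s / t))) for n, s in zip(v.voxels.shape, v.spacing)
    )
    default = 0.0 if is_mask else float(v.voxels.min())
    arr = _resample(v.voxels.astype(np.float32), v.spacing, v.origin, out_shape, (t, t, t), interpolation, default)
    if is_mask:
        return BinaryMask((arr > 0.5).astype(np.uint8), (t, t, t), v.origin)
    return Volume(arr, (t, t, t), v.origin)


def resample_to_shape(
    v: Volume | BinaryMask, out_shape: tuple[int, int, int], interpolation: str | None = None
) -> Volume | BinaryMask:
    """Resample onto a fixed grid shape covering the same physical extent."""
    out_shape = tuple(int(s) for s in out_shape)
    if any(s < 1 for s in out_shape):
        raise ValueError(f"output shape must be >= 1 per axis, got {out_shape}")
    is_mask = isinstance(v, BinaryMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if out_shape == v.voxels.shape:
        cls = BinaryMask if is_mask else Volume
        return cls(v.voxels.copy(), v.spacing, v.origin)
    out_spacing = tuple(n * s / m for n, s, m in zip(v.voxels.shape, v.spacing, out_shape))
    default = 0.0 if is_mask else float(v.voxels.min())
    arr = _resample(v.voxels.astype(np.float32), v.spacing, v.origin, out_shape, out_spacing, interpolation, default)
    if is_mask:
        return BinaryMask((arr > 0.5).astype(np.uint8), out_spacing, v.origin)
    return Volume(arr, out_spacing, v.origin)


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(m: SurfaceMesh, path: str | os.PathLike, mode: Literal["binary", "ascii"] = "binary") -> None:
    """Export a mesh as STL (binary little-endian by default)."""
    if m.n_faces == 0:
        raise ValueError("cannot export an empty mesh")
    tm = m.to_trimesh()
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    out = Path(path)
    if isinstance(data, str):
        out.write_text(data)
    else:
        out.write_bytes(data)


def read_stl(path: str | os.PathLike) -> SurfaceMesh:
    """Read an STL file back into a :class:`SurfaceMesh` (merging duplicate
    vertices, since STL stores a triangle soup)."""
    tm = trimesh.load(str(path), file_type="stl", process=True)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
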