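"""Two-stage coarse-to-fine inference: Volume -> BinaryMask -> SurfaceMesh.

Working principle: the input scan is resampled to isotropic voxels; a
first U-Net sees the whole (fixed-size, downsampled) volume and produces
a rough low-resolution segmentation; full-resolution patches are proposed
over that rough foreground; a second U-Net segments each patch, and the
patch predictions are stitched (overlaps averaged) into a full-resolution
probability map. Binarization, largest-connected-component selection,
marching cubes and volume-preserving mesh smoothing produce the final
mask and 3D model.

Every stage is deterministic, so running the pipeline twice on the same
input with the same weights yields byte-identical outputs (the model's
test-retest property).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import measure
import trimesh.smoothing

from .errors import ConfigError, GeometryError, ShapeError
from .unet3d import UNet3D, normalize_hu
from .volume_io import BinaryMask, SurfaceMesh, Volume, resample_isotropic, resample_to_shape

__all__ = [
    "PipelineConfig",
    "Patch",
    "RunReport",
    "PipelineResult",
    "coarse_segment",
    "propose_patches",
    "fine_segment_and_stitch",
    "postprocess",
    "extract_mesh",
    "run_pipeline",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass(frozen=True)
class PipelineConfig:
    target_spacing_mm: float = 0.4
    coarse_fixed_size: tuple[int, int, int] = (32, 32, 32)
    patch_size: tuple[int, int, int] = (32, 32, 32)
    patch_stride: tuple[int, int, int] = (16, 16, 16)
    prob_threshold: float = 0.5
    smoothing_method: str = "taubin"  # or "none"
    smoothing_iterations: int = 10
    min_component_voxels: int = 1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ConfigError("prob_threshold must lie strictly between 0 and 1")
        if any(s > p for s, p in zip(self.patch_stride, self.patch_size)):
            raise ConfigError("patch_stride must not exceed patch_size")
        for name in ("coarse_fixed_size", "patch_size"):
            if any(d % 8 for d in getattr(self, name)):
                raise ConfigError(f"{name} must be divisible by 8, got {getattr(self, name)}")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Patch:
    """An axis-aligned full-resolution patch (0-based voxel corner)."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))


@dataclass
class RunReport:
    patch_count: int = 0
    component_sizes: list[int] = field(default_factory=list)
    failed: bool = False
    elapsed_s: dict[str, float] = field(default_factory=dict)
    mesh_open_boundary: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    mask: BinaryMask            # on the resampled (isotropic) grid
    mask_native: BinaryMask     # resampled back to the input grid
    mesh: SurfaceMesh | None
    report: RunReport


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def coarse_segment(v: Volume, coarse_net: UNet3D, cfg: PipelineConfig) -> np.ndarray:
    """Low-resolution segmentation upsampled back to the full grid.

    The volume is downsampled to ``cfg.coarse_fixed_size``, pushed through
    the coarse network, and the probability map is trilinearly upsampled to
    the input grid. Values stay in [0, 1].
    """
    small = resample_to_shape(v, cfg.coarse_fixed_size, interpolation="linear")
    p_small = coarse_net.predict(normalize_hu(small.voxels))
    if p_small.shape == v.shape:
        return p_small
    prob_vol = Volume(p_small.astype(np.float32), small.spacing, small.origin)
    up = resample_to_shape(prob_vol, v.shape, interpolation="linear")
    return np.clip(up.voxels.astype(np.float64), 0.0, 1.0)


def propose_patches(coarse: np.ndarray, cfg: PipelineConfig, grid_shape=None) -> list[Patch]:
    """Tile the bounding box of the thresholded coarse foreground.

    Patches of ``cfg.patch_size`` are placed at ``cfg.patch_stride`` over
    the foreground bounding box; origins are shifted (never shrunk) to stay
    inside the grid; only patches intersecting the foreground are kept,
    in lexicographic origin order. Empty foreground returns [].
    """
    coarse = np.asarray(coarse)
    shape = tuple(grid_shape) if grid_shape is not None else coarse.shape
    size = tuple(int(s) for s in cfg.patch_size)
    if any(p > s for p, s in zip(size, shape)):
        raise GeometryError(f"patch {size} larger than grid {shape}")
    fg = coarse >= cfg.prob_threshold
    if not fg.any():
        return []
    idx = np.argwhere(fg)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    starts_per_axis = []
    for a in range(3):
        starts = list(range(int(lo[a]), int(hi[a]) + 1, int(cfg.patch_stride[a])))
        starts = [min(max(s, 0), shape[a] - size[a]) for s in starts]
        starts_per_axis.append(sorted(set(starts)))
    patches = []
    for i in starts_per_axis[0]:
        for j in starts_per_axis[1]:
            for k in starts_per_axis[2]:
                p = Patch((i, j, k), size)
                if fg[p.slices].any():
                    patches.append(p)
    return patches


def fine_segment_and_stitch(
    v: Volume, patches: list[Patch], fine_net: UNet3D, cfg: PipelineConfig
) -> np.ndarray:
    """Predict each patch independently and average overlapping voxels.

    Voxels covered by no patch get probability exactly 0.
    """
    x = normalize_hu(v.voxels)
    acc = np.zeros(v.shape, dtype=np.float64)
    cnt = np.zeros(v.shape, dtype=np.int32)
    for p in patches:
        sl = p.slices
        patch_x = x[sl]
        if patch_x.shape != tuple(p.size):
            raise ShapeError(f"patch at {p.origin} leaves the grid {v.shape}")
        acc[sl] += fine_net.predict(patch_x)
        cnt[sl] += 1
    out = np.zeros_like(acc)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


def postprocess(p: np.ndarray, cfg: PipelineConfig, spacing, origin=(0.0, 0.0, 0.0)):
    """Binarize (``>= prob_threshold``) and keep the largest connected
    component (26-connectivity by default).

    Returns ``(mask, component_sizes, failed)``; an empty post-threshold
    foreground (or one below ``min_component_voxels``) yields an all-zero
    mask flagged as a failed prediction (clinical class E). When two
    components tie in size the one whose first voxel comes first in raster
    (lexicographic index) order is kept.
    """
    binary = np.asarray(p) >= cfg.prob_threshold
    labels, n = ndimage.label(binary, structure=_structure(cfg.connectivity))
    if n == 0:
        return BinaryMask(np.zeros(binary.shape, np.uint8), spacing, origin), [], True
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    sizes = sorted((int(c) for c in counts[1:] if c > 0), reverse=True)
    # argmax returns the lowest label among ties = first in raster order
    winner = int(counts.argmax())
    if counts[winner] < cfg.min_component_voxels:
        return BinaryMask(np.zeros(binary.shape, np.uint8), spacing, origin), sizes, True
    mask = (labels == winner).astype(np.uint8)
    return BinaryMask(mask, spacing, origin), sizes, False


def extract_mesh(m: BinaryMask, cfg: PipelineConfig) -> SurfaceMesh:
    """Marching cubes (iso-level 0.5) on the binary grid, vertices in mm
    world coordinates, followed by volume-preserving Taubin smoothing.

    A mask touching the grid boundary produces an open surface; the mesh
    is returned with ``open_boundary=True`` in that case.
    """
    if m.count() == 0:
        raise ValueError("cannot extract a mesh from an empty mask")
    vox = m.voxels
    touches = bool(
        vox[0].any() or vox[-1].any()
        or vox[:, 0].any() or vox[:, -1].any()
        or vox[:, :, 0].any() or vox[:, :, -1].any()
    )
    origin = np.asarray(m.origin, dtype=float)
    if vox.min() == vox.max():
        # degenerate all-foreground mask: clip the surface at the grid
        # boundary by padding one background voxel on every side
        vox = np.pad(vox, 1)
        origin = origin - np.asarray(m.spacing)
    verts, faces, _, _ = measure.marching_cubes(
        vox.astype(np.float32), level=0.5, spacing=tuple(m.spacing)
    )
    verts = verts + origin[None, :]
    mesh = SurfaceMesh(verts, faces, open_boundary=touches)
    if cfg.smoothing_method == "taubin" and cfg.smoothing_iterations > 0:
        tm = mesh.to_trimesh()
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53, iterations=cfg.smoothing_iterations)
        mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), open_boundary=touches)
    return mesh


def run_pipeline(
    v: Volume,
    coarse_net: UNet3D,
    fine_net: UNet3D,
    cfg: PipelineConfig | None = None,
    extract_surface: bool = True,
) -> PipelineResult:
    """Full chain: resample -> coarse -> patches -> fine -> postprocess ->
    mesh. Returns masks on both the isotropic and the native grid, the
    smoothed surface (None on failure), and a run report with stage
    timings, patch count and component sizes."""
    cfg = cfg or PipelineConfig()
    report = RunReport()
    t0 = time.perf_counter()
    iso = resample_isotropic(v, cfg.target_spacing_mm)
    report.elapsed_s["resample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    coarse = coarse_segment(iso, coarse_net, cfg)
    report.elapsed_s["coarse"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    patches = propose_patches(coarse, cfg)
    report.patch_count = len(patches)
    prob = fine_segment_and_stitch(iso, patches, fine_net, cfg)
    report.elapsed_s["fine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mask, sizes, failed = postprocess(prob, cfg, iso.spacing, iso.origin)
    report.component_sizes = sizes
    report.failed = failed
    report.elapsed_s["postprocess"] = time.perf_counter() - t0

    if mask.shape != v.shape:
        native = resample_to_shape(mask, v.shape, interpolation="nearest")
        native = BinaryMask(native.voxels, v.spacing, v.origin)
    else:
        native = BinaryMask(mask.voxels.copy(), v.spacing, v.origin)

    mesh = None
    if extract_surface and not failed:
        t0 = time.perf_counter()
        mesh = extract_mesh(mask, cfg)
        report.mesh_open_boundary = mesh.open_boundary
        report.elapsed_s["mesh"] = time.perf_counter() - t0
    return PipelineResult(mask, native, mesh, report)
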