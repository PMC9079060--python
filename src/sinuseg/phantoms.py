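"""Synthetic CBCT sinus phantoms with paired ground truth.

Every other module in the package is trained and tested against these
phantoms, so they encode the anatomy the segmentation task cares about:

* an air-filled sinus cavity (about -1000 HU), modelled as a rotated
  superellipsoid so the "pyramidal" shape variability of real sinuses is
  captured with a closed-form volume;
* a cortical bone shell around the cavity (high HU);
* an optional mucosal lining on the inner wall (soft-tissue HU) -- the
  lining is *not* part of the ground truth, mirroring how mucosal
  thickening narrows the air space in real scans;
* an optional ostium: a narrow air channel connecting the cavity to a
  nasal airway near one face of the grid. The ground truth stops at the
  channel mouth: only the cavity interior is labelled, the channel and the
  nasal airway are excluded even though they are air and 26-connected to
  the cavity. This makes naive HU thresholding insufficient and forces a
  model to learn the anatomical cut;
* additive Gaussian noise on top of the piecewise-constant HU levels.

Intensities are assigned by voxel-centre membership, so on a noiseless
phantom the air window and the geometry agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .volume_io import BinaryMask, Volume

__all__ = [
    "HuLevels",
    "OstiumSpec",
    "JitterSpec",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "threshold_air_mask",
]


@dataclass(frozen=True)
class HuLevels:
    """Tissue intensity levels in HU. Only the air window (-1024..-200) is
    fixed by the labelling convention; the rest are standard CT values."""

    air: float = -1000.0
    soft_tissue: float = 40.0
    mucosa: float = 30.0
    bone: float = 1000.0


@dataclass(frozen=True)
class OstiumSpec:
    """Air channel from the sinus cavity to a nasal airway.

    The nasal airway is a flattened superellipsoid slab near the low-j face
    of the grid (standing in for the nasal cavity at the edge of a CBCT
    field of view); the channel is a cylinder of ``radius_mm`` between the
    two cavity centres.
    """

    radius_mm: float = 0.8
    nasal_center_mm: tuple[float, float, float] = (12.8, 4.4, 12.8)
    nasal_semi_axes_mm: tuple[float, float, float] = (6.0, 2.2, 14.0)
    nasal_exponent: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.4
    semi_axes_mm: tuple[float, float, float] = (5.2, 4.6, 5.2)
    center_mm: tuple[float, float, float] = (12.8, 15.2, 12.8)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    exponent: float = 2.2
    ostium: OstiumSpec | None = OstiumSpec()
    thickening_mm: float = 0.0
    bone_shell_mm: float = 1.2
    hu_levels: HuLevels = HuLevels()
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise GeometryError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        if self.thickening_mm < 0:
            raise GeometryError("thickening_mm must be >= 0")
        if self.thickening_mm >= min(self.semi_axes_mm):
            raise GeometryError("mucosal lining would fill the whole cavity")
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be >= 0")
        if self.bone_shell_mm < 0:
            raise GeometryError("bone_shell_mm must be >= 0")
        # conservative fit check: bounding sphere of cavity + shell inside grid
        r = max(self.semi_axes_mm) + self.bone_shell_mm
        extent = np.asarray(self.grid_shape, float) * self.spacing_mm
        c = np.asarray(self.center_mm)
        if (c - r < 0).any() or (c + r > extent).any():
            raise GeometryError(
                f"cavity (radius+shell {r:.1f} mm at {self.center_mm}) does not fit "
                f"inside the {tuple(extent)} mm grid"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("ostium") is not None:
            ost = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                   for k, v in dict(d["ostium"]).items()}
            d["ostium"] = OstiumSpec(**ost)
        if "hu_levels" in d:
            d["hu_levels"] = HuLevels(**d["hu_levels"])
        for key in ("grid_shape", "semi_axes_mm", "center_mm", "rotation_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomSample:
    volume: Volume
    truth: BinaryMask
    spec: PhantomSpec


def _rotation_matrix(deg: Sequence[float]) -> np.ndarray:
    a, b, c = np.deg2rad(deg)
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    r0 = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    r1 = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    r2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return r0 @ r1 @ r2


def _superellipsoid_inside(
    coords: np.ndarray, center, semi_axes, exponent: float, rot: np.ndarray | None = None
) -> np.ndarray:
    """Boolean grid of voxel centres inside |q0/a|^e + |q1/b|^e + |q2/c|^e <= 1."""
    q = coords - np.asarray(center, float)
    if rot is not None:
        q = q @ rot  # rotate world into body frame (rot columns = body axes)
    s = np.zeros(q.shape[:-1])
    for ax in range(3):
        s += np.abs(q[..., ax] / semi_axes[ax]) ** exponent
    return s <= 1.0


def _voxel_centers(shape, spacing: float) -> np.ndarray:
    axes = [np.arange(n) * spacing for n in shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack(g, axis=-1)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom volume and its ground-truth mask.

    Deterministic given ``spec.seed`` (the seed only drives the noise).
    """
    hu = spec.hu_levels
    coords = _voxel_centers(spec.grid_shape, spec.spacing_mm)
    rot = _rotation_matrix(spec.rotation_deg)

    inner_axes = tuple(a - spec.thickening_mm for a in spec.semi_axes_mm)
    shell_axes = tuple(a + spec.bone_shell_mm for a in spec.semi_axes_mm)
    inner = _superellipsoid_inside(coords, spec.center_mm, inner_axes, spec.exponent, rot)
    outer = _superellipsoid_inside(coords, spec.center_mm, spec.semi_axes_mm, spec.exponent, rot)
    shell = _superellipsoid_inside(coords, spec.center_mm, shell_axes, spec.exponent, rot)
    if not inner.any():
        raise GeometryError("cavity contains no voxel centres; grid too coarse")

    vol = np.full(spec.grid_shape, hu.soft_tissue, dtype=np.float32)
    vol[shell] = hu.bone
    if spec.ostium is not None:
        ost = spec.ostium
        nasal = _superellipsoid_inside(
            coords, ost.nasal_center_mm, ost.nasal_semi_axes_mm, ost.nasal_exponent
        )
        nasal_shell = _superellipsoid_inside(
            coords,
            ost.nasal_center_mm,
            tuple(a + spec.bone_shell_mm for a in ost.nasal_semi_axes_mm),
            ost.nasal_exponent,
        )
        vol[nasal_shell & ~shell] = hu.bone
    vol[outer & ~inner] = hu.mucosa  # mucosal lining (excluded from truth)
    vol[inner] = hu.air
    if spec.ostium is not None:
        # cylindrical channel between cavity centre and nasal centre,
        # carved as air only *outside* the cavity interior
        p0 = np.asarray(spec.center_mm, float)
        p1 = np.asarray(ost.nasal_center_mm, float)
        d = p1 - p0
        t = np.clip(((coords - p0) @ d) / (d @ d), 0.0, 1.0)
        closest = p0 + t[..., None] * d
        channel = np.linalg.norm(coords - closest, axis=-1) <= ost.radius_mm
        vol[channel & ~inner] = hu.air
        vol[nasal] = hu.air

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape).astype(np.float32)

    sp = (spec.spacing_mm,) * 3
    return PhantomSample(Volume(vol, sp), BinaryMask(inner.astype(np.uint8), sp), spec)


@dataclass(frozen=True)
class JitterSpec:
    """Per-sample parameter ranges for dataset generation. All ranges admit
    the base geometry; zero-width ranges reproduce it exactly."""

    semi_axes_frac: float = 0.15
    rotation_deg: float = 15.0
    center_mm: float = 1.0
    thickening_range_mm: tuple[float, float] = (0.8, 1.6)
    thickening_prob: float = 0.5
    exponent_range: tuple[float, float] = (2.0, 2.6)


def generate_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: JitterSpec | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with jittered geometry, reproducibly.

    Each sample gets an independent noise seed derived from ``seed`` via a
    spawned :class:`numpy.random.SeedSequence`, so two calls with the same
    arguments return bit-identical samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    jit = jitter if jitter is not None else JitterSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        axes = tuple(
            a * (1.0 + rng.uniform(-jit.semi_axes_frac, jit.semi_axes_frac))
            for a in base.semi_axes_mm
        )
        rotation = tuple(rng.uniform(-jit.rotation_deg, jit.rotation_deg) for _ in range(3))
        center = tuple(
            c + rng.uniform(-jit.center_mm, jit.center_mm) for c in base.center_mm
        )
        thick = 0.0
        if rng.uniform() < jit.thickening_prob:
            thick = float(rng.uniform(*jit.thickening_range_mm))
        expo = float(rng.uniform(*jit.exponent_range))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            semi_axes_mm=axes,
            rotation_deg=rotation,
            center_mm=center,
            thickening_mm=thick,
            exponent=expo,
            seed=noise_seed,
        )
        try:
            samples.append(generate_phantom(spec))
        except GeometryError as exc:
            raise GeometryError(f"sample {i}: {exc}") from exc
    return samples


def split_dataset(
    samples: list[PhantomSample], fractions: tuple[float, float, float]
) -> tuple[list[PhantomSample], list[PhantomSample], list[PhantomSample]]:
    """Partition into disjoint (train, val, test) lists by rounded fractions;
    the test split absorbs the rounding remainder."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(samples)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    if n_train + n_val > n:
        raise ValueError("split leaves no room for a test partition")
    return samples[:n_train], samples[n_train : n_train + n_val], samples[n_train + n_val :]


def threshold_air_mask(v: Volume, lo: float = -1024.0, hi: float = -200.0) -> BinaryMask:
    """Air mask by HU window: voxel is 1 iff ``lo <= HU <= hi`` (inclusive).

    This is the first step of the semi-automatic labelling workflow the
    ground truth convention derives from.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (v.voxels >= lo) & (v.voxels <= hi)
    return BinaryMask(mask.astype(np.uint8), v.spacing, v.origin)


def largest_air_component(mask: BinaryMask) -> BinaryMask:
    """Convenience: restrict an air mask to its largest 26-connected component."""
    labels, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), int))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == counts.argmax()
    return BinaryMask(keep.astype(np.uint8), mask.spacing, mask.origin)
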