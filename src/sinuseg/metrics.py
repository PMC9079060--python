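"""Segmentation accuracy metrics: confusion counts, DSC, IoU, 95 %
Hausdorff distance and RMS surface distance.

Overlap metrics come from the voxel-wise confusion matrix:

    DSC = 2|X ∩ Y| / (|X| + |Y|) = 2TP / (2TP + FP + FN)
    IoU = |X ∩ Y| / |X ∪ Y|      = TP / (TP + FP + FN)

(DSC and IoU are linked by DSC = 2·IoU / (1 + IoU).)

Distance metrics operate in mm. For masks, the surface is the set of
foreground voxels with at least one background 6-neighbour (the thinnest
boundary shell). The 95 % Hausdorff distance is the 95th percentile
(linear interpolation between order statistics) of the *pooled* symmetric
closest-point distance set — both directions a→b and b→a — which makes it
order-independent and robust to a small fraction of outliers. The RMS
surface distance is sqrt(mean(x_i²)) of closest-point distances from each
vertex of one mesh to the other *surface* (exact point-to-triangle), and
is symmetrized as the mean of the two directed RMS values.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import MetricError, ShapeError
from .volume_io import BinaryMask, SurfaceMesh

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "dsc",
    "iou",
    "mask_surface_points",
    "hd95",
    "rms_distance",
    "evaluate_pair",
    "evaluate_batch",
    "summary_to_csv",
]


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    dsc: float
    iou: float
    hd95_mm: float | None = None
    rms_mm: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_bool(m) -> np.ndarray:
    if isinstance(m, BinaryMask):
        return m.voxels.astype(bool)
    return np.asarray(m).astype(bool)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Exact voxel counts (TP, TN, FP, FN)."""
    p, t = _as_bool(pred), _as_bool(truth)
    _check_shapes(p, t)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return tp, tn, fp, fn


def dsc(pred, truth) -> float:
    """Dice similarity coefficient; 1 means complete overlap. Two empty
    masks are defined as 1 (perfect agreement on absence), with a warning."""
    tp, _, fp, fn = confusion_counts(pred, truth)
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("DSC of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * tp / denom


def iou(pred, truth) -> float:
    """Intersection over union (Jaccard index); 1 means perfect overlap."""
    tp, _, fp, fn = confusion_counts(pred, truth)
    denom = tp + fp + fn
    if denom == 0:
        warnings.warn("IoU of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return tp / denom


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------

def mask_surface_points(m: BinaryMask) -> np.ndarray:
    """World coordinates (mm) of boundary voxels: foreground voxels with at
    least one background 6-neighbour (grid edges count as background)."""
    vox = m.voxels.astype(bool)
    core = ndimage.binary_erosion(vox, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    boundary = vox & ~core
    idx = np.argwhere(boundary)
    return idx * np.asarray(m.spacing)[None, :] + np.asarray(m.origin)[None, :]


def _surface_coords(x, spacing=None) -> np.ndarray:
    if isinstance(x, BinaryMask):
        pts = mask_surface_points(x)
    elif isinstance(x, SurfaceMesh):
        pts = x.vertices
    else:
        pts = np.asarray(x, dtype=float).reshape(-1, 3)
        if spacing is not None:
            pts = pts * np.asarray(spacing)[None, :]
    if len(pts) == 0:
        raise MetricError("empty surface: distance metrics are undefined")
    return pts


def hd95(a, b, spacing=None) -> float:
    """95 % Hausdorff distance in mm between two masks, meshes, or voxel
    index arrays (scaled by ``spacing``). Pools the two directed
    closest-point distance sets and takes their 95th percentile."""
    pa, pb = _surface_coords(a, spacing), _surface_coords(b, spacing)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def hausdorff_exact(a, b, spacing=None) -> float:
    """Classic (maximum) symmetric Hausdorff distance; hd95 <= this."""
    pa, pb = _surface_coords(a, spacing), _surface_coords(b, spacing)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(max(d_ab.max(), d_ba.max()))


def _closest_triangle_dist(points: np.ndarray, tri: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Distance from each point to the nearest point on any triangle.

    Vectorized closest-point-on-triangle (region classification via
    barycentric clamping); exact, not vertex-sampled.
    """
    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, bc = B - A, C - A, C - B
    len_ab = np.maximum((ab * ab).sum(-1), 1e-300)
    len_ac = np.maximum((ac * ac).sum(-1), 1e-300)
    len_bc = np.maximum((bc * bc).sum(-1), 1e-300)
    # triangle-plane basis Gram matrix for the interior projection
    aa = (ab * ab).sum(-1)
    cc = (ac * ac).sum(-1)
    acdot = (ab * ac).sum(-1)
    det = np.maximum(aa * cc - acdot**2, 1e-300)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        P = points[s : s + chunk][:, None, :]  # (n,1,3)
        ap, bp = P - A[None], P - B[None]
        # clamped projections onto the three edges (include the vertices)
        t1 = np.clip((ap * ab[None]).sum(-1) / len_ab, 0, 1)
        t2 = np.clip((ap * ac[None]).sum(-1) / len_ac, 0, 1)
        t3 = np.clip((bp * bc[None]).sum(-1) / len_bc, 0, 1)
        d_e1 = ((P - (A[None] + t1[..., None] * ab[None])) ** 2).sum(-1)
        d_e2 = ((P - (A[None] + t2[..., None] * ac[None])) ** 2).sum(-1)
        d_e3 = ((P - (B[None] + t3[..., None] * bc[None])) ** 2).sum(-1)
        best = np.minimum(np.minimum(d_e1, d_e2), d_e3)
        # interior projection in barycentric coordinates, valid when inside
        pa = (ap * ab[None]).sum(-1)
        pc = (ap * ac[None]).sum(-1)
        v = (cc * pa - acdot * pc) / det
        w = (aa * pc - acdot * pa) / det
        inside = (v >= 0) & (w >= 0) & (v + w <= 1)
        proj = A[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        d_in = np.where(inside, ((P - proj) ** 2).sum(-1), np.inf)
        best = np.minimum(best, d_in)
        out[s : s + chunk] = np.sqrt(best.min(axis=1))
    return out


def rms_distance(a: SurfaceMesh, b: SurfaceMesh) -> float:
    """Symmetrized RMS surface distance in mm: sqrt(mean(x²)) of
    vertex-to-surface distances, averaged over the two directions."""
    for m in (a, b):
        if not isinstance(m, SurfaceMesh) or m.n_faces == 0:
            raise MetricError("rms_distance requires two non-empty meshes")
    tri_a = a.vertices[a.faces]
    tri_b = b.vertices[b.faces]
    d_ab = _closest_triangle_dist(a.vertices, tri_b)
    d_ba = _closest_triangle_dist(b.vertices, tri_a)
    rms_ab = float(np.sqrt(np.mean(d_ab**2)))
    rms_ba = float(np.sqrt(np.mean(d_ba**2)))
    return 0.5 * (rms_ab + rms_ba)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def evaluate_pair(
    pred: BinaryMask,
    truth: BinaryMask,
    pred_mesh: SurfaceMesh | None = None,
    truth_mesh: SurfaceMesh | None = None,
) -> MetricsReport:
    """Full report for one pair of segmentations on the same grid.

    Distance metrics need non-empty inputs; they are reported as None when
    either mask is empty (overlap metrics are still defined). If meshes are
    not supplied, the RMS is computed between raw (unsmoothed) marching-
    cubes surfaces of the two masks.
    """
    _check_shapes(pred.voxels, truth.voxels)
    if pred.spacing != truth.spacing:
        raise ShapeError(f"mask spacings differ: {pred.spacing} vs {truth.spacing}")
    tp, tn, fp, fn = confusion_counts(pred, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d, j = dsc(pred, truth), iou(pred, truth)
    hd = rms = None
    if pred.count() and truth.count():
        hd = hd95(pred, truth)
        if pred_mesh is None or truth_mesh is None:
            from skimage import measure

            def _mc(m):
                v, f, _, _ = measure.marching_cubes(
                    m.voxels.astype(np.float32), 0.5, spacing=tuple(m.spacing)
                )
                return SurfaceMesh(v + np.asarray(m.origin)[None, :], f)

            pred_mesh = pred_mesh or _mc(pred)
            truth_mesh = truth_mesh or _mc(truth)
        rms = rms_distance(pred_mesh, truth_mesh)
    return MetricsReport(tp, tn, fp, fn, d, j, hd, rms)


def evaluate_batch(pairs) -> tuple[list[MetricsReport], dict]:
    """Evaluate a sequence of (pred, truth) or (pred, truth, pred_mesh,
    truth_mesh) tuples; returns per-case reports plus mean/SD/min/max
    summary rows per metric (SD is the population SD of the batch)."""
    reports = [evaluate_pair(*pair) for pair in pairs]
    if not reports:
        raise ValueError("empty batch")
    summary = {}
    for name in ("dsc", "iou", "hd95_mm", "rms_mm"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            arr = np.asarray(vals, dtype=float)
            summary[name] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std()),
                "min": float(arr.min()),
                "max": float(arr.max()),
            }
    return reports, summary


def summary_to_csv(summary: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "mean", "sd", "min", "max"])
        for name, row in summary.items():
            w.writerow([name, row["mean"], row["sd"], row["min"], row["max"]])
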