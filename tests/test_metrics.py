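import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sinuseg.errors import MetricError, ShapeError
from sinuseg.metrics import (
    confusion_counts,
    dsc,
    evaluate_batch,
    evaluate_pair,
    hausdorff_exact,
    hd95,
    iou,
    mask_surface_points,
    rms_distance,
    _closest_triangle_dist,
)
from sinuseg.volume_io import BinaryMask, SurfaceMesh


def mask(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), spacing)


def random_pair(seed, shape=(4, 4, 4), p=0.4):
    r = np.random.default_rng(seed)
    return (r.uniform(size=shape) < p), (r.uniform(size=shape) < p)


class TestConfusion:
    def test_equal_masks(self, rng):
        m = (rng.uniform(size=(5, 5, 5)) < 0.3).astype(np.uint8)
        tp, tn, fp, fn = confusion_counts(mask(m), mask(m))
        assert fp == fn == 0 and tp == m.sum() and tp + tn == m.size

    def test_complement(self, rng):
        m = (rng.uniform(size=(5, 5, 5)) < 0.5).astype(np.uint8)
        tp, tn, fp, fn = confusion_counts(mask(1 - m), mask(m))
        assert tp == tn == 0

    def test_enumerated_2x2x1_grid(self):
        truth = np.zeros((2, 2, 1), np.uint8)
        truth[0, 0, 0] = truth[1, 0, 0] = truth[0, 1, 0] = 1
        pred = np.zeros((2, 2, 1), np.uint8)
        pred[1, 0, 0] = pred[0, 1, 0] = pred[1, 1, 0] = 1
        tp, tn, fp, fn = confusion_counts(mask(pred), mask(truth))
        assert (tp, fp, fn, tn) == (2, 1, 1, 0)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestOverlapMetrics:
    def test_counting_example(self):
        # |X|=3, |Y|=2, |X∩Y|=2 -> DSC 0.8
        x = np.zeros((3, 1, 1), np.uint8)
        x[:] = 1
        y = np.zeros((3, 1, 1), np.uint8)
        y[:2] = 1
        assert dsc(mask(x), mask(y)) == pytest.approx(0.8)

    def test_iou_counting_example(self):
        # |X∩Y|=2, |X∪Y|=3
        x = np.array([1, 1, 1, 0]).reshape(4, 1, 1)
        y = np.array([0, 1, 1, 0]).reshape(4, 1, 1)
        assert iou(mask(x), mask(y)) == pytest.approx(2 / 3)

    def test_identical_masks_score_one(self, rng):
        m = (rng.uniform(size=(4, 4, 4)) < 0.5) | True  # non-empty
        assert dsc(mask(m), mask(m)) == 1.0
        assert iou(mask(m), mask(m)) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((2, 2, 2), np.uint8)
        b = np.zeros((2, 2, 2), np.uint8)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dsc(mask(a), mask(b)) == 0.0

    def test_both_empty_defined_one_with_warning(self):
        e = np.zeros((2, 2, 2), np.uint8)
        with pytest.warns(UserWarning):
            assert dsc(mask(e), mask(e)) == 1.0

    def test_symmetry_and_set_arithmetic_brute_force(self):
        for seed in range(200):
            a, b = random_pair(seed, shape=(6, 6, 6))
            inter = np.sum(a & b)
            union = np.sum(a | b)
            if union == 0:
                continue
            d, j = dsc(a, b), iou(a, b)
            assert d == dsc(b, a) and j == iou(b, a)
            assert j == inter / union
            assert d == 2 * inter / (a.sum() + b.sum())

    @given(st.integers(0, 10**6))
    @settings(max_examples=1000, deadline=None)
    def test_dsc_iou_identity(self, seed):
        a, b = random_pair(seed)
        if not (a | b).any():
            return
        assert abs(dsc(a, b) - 2 * iou(a, b) / (1 + iou(a, b))) < 1e-12

    def test_flipping_fn_to_tp_never_decreases_dsc(self):
        for seed in range(50):
            a, b = random_pair(seed, p=0.5)
            fn_vox = np.argwhere(~a & b)
            if not len(fn_vox) or not (a | b).any():
                continue
            d0 = dsc(a, b) if a.any() or b.any() else 1.0
            a2 = a.copy()
            a2[tuple(fn_vox[0])] = True
            assert dsc(a2, b) >= d0


class TestHd95:
    def test_identical_masks_zero(self, noiseless_phantom):
        assert hd95(noiseless_phantom.truth, noiseless_phantom.truth) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[2, 2, 2] = 1
        b[5, 2, 2] = 1
        assert hd95(mask(a, (0.5,) * 3), mask(b, (0.5,) * 3)) == pytest.approx(1.5)

    def test_hd95_bounded_by_exact_hausdorff_brute_force(self):
        for seed in range(30):
            a, b = random_pair(seed, shape=(5, 5, 5), p=0.3)
            if not a.any() or not b.any():
                continue
            ma, mb = mask(a, (0.7,) * 3), mask(b, (0.7,) * 3)
            # brute-force all-pairs directed distances over boundary points
            pa, pb = mask_surface_points(ma), mask_surface_points(mb)
            dmat = np.linalg.norm(pa[:, None] - pb[None], axis=-1)
            exact = max(dmat.min(axis=1).max(), dmat.min(axis=0).max())
            assert hausdorff_exact(ma, mb) == pytest.approx(exact, abs=1e-9)
            assert hd95(ma, mb) <= exact + 1e-9
            # pooled-percentile oracle
            pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
            assert hd95(ma, mb) == pytest.approx(np.percentile(pooled, 95), abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(MetricError):
            hd95(mask(np.zeros((3, 3, 3))), mask(np.ones((3, 3, 3))))

    def test_surface_extraction_is_thin_boundary(self):
        solid = np.zeros((7, 7, 7), np.uint8)
        solid[1:6, 1:6, 1:6] = 1
        pts = mask_surface_points(mask(solid))
        assert len(pts) == 5**3 - 3**3  # shell of a 5^3 cube


def _plane_mesh(z=0.0, n=6):
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(verts, np.asarray(faces))


class TestRms:
    def test_identical_meshes_zero(self):
        m = _plane_mesh()
        assert rms_distance(m, m) == 0.0

    def test_rms_formula_hand_evaluation(self):
        # sqrt((1 + 4 + 9)/3)
        x = np.array([1.0, 2.0, 3.0])
        assert np.sqrt(np.mean(x**2)) == pytest.approx(2.160246899469287)

    def test_offset_plane_distance(self):
        a, b = _plane_mesh(0.0), _plane_mesh(0.25)
        assert rms_distance(a, b) == pytest.approx(0.25, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = _plane_mesh(0.0), _plane_mesh(0.4, n=5)
        assert rms_distance(a, b) == rms_distance(b, a)

    def test_point_triangle_oracle_dense_sampling(self, rng):
        """Exact closest-triangle distance vs brute-force sampling of many
        points on the triangles (upper bound, converging from above)."""
        tri = rng.normal(size=(4, 3, 3))
        pts = rng.normal(size=(20, 3)) * 2
        exact = _closest_triangle_dist(pts, tri)
        # dense barycentric sampling
        u = np.linspace(0, 1, 60)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1
        uu, vv = uu[keep], vv[keep]
        best = np.full(len(pts), np.inf)
        for t in tri:
            samples = (1 - uu - vv)[:, None] * t[0] + uu[:, None] * t[1] + vv[:, None] * t[2]
            d = np.linalg.norm(pts[:, None] - samples[None], axis=-1).min(axis=1)
            best = np.minimum(best, d)
        assert np.all(exact <= best + 1e-9)
        assert np.allclose(exact, best, atol=0.06)  # sampling resolution bound

    def test_empty_mesh_rejected(self):
        with pytest.raises(MetricError):
            rms_distance(_plane_mesh(), SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int)))


class TestEvaluate:
    def test_report_identity_and_batch_stats(self):
        pairs = []
        for seed in range(8):
            a, b = random_pair(seed, shape=(6, 6, 6))
            if not a.any() or not b.any():
                continue
            pairs.append((mask(a), mask(b)))
        reports, summary = evaluate_batch(pairs)
        for r in reports:
            assert r.tp + r.tn + r.fp + r.fn == 6**3
            assert r.iou <= r.dsc
            assert abs(r.dsc - 2 * r.iou / (1 + r.iou)) < 1e-12
        assert summary["dsc"]["min"] <= summary["dsc"]["mean"] <= summary["dsc"]["max"]

    def test_batch_of_identical_pairs(self, noiseless_phantom):
        t = noiseless_phantom.truth
        reports, summary = evaluate_batch([(t, t), (t, t)])
        assert summary["dsc"]["mean"] == 1.0 and summary["dsc"]["sd"] == 0.0
        assert summary["hd95_mm"]["mean"] == 0.0

    def test_single_pair_mean_equals_min_max(self, noiseless_phantom):
        t = noiseless_phantom.truth
        a = BinaryMask(np.roll(t.voxels, 1, axis=0), t.spacing)
        _, summary = evaluate_batch([(a, t)])
        row = summary["dsc"]
        assert row["mean"] == row["min"] == row["max"]
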