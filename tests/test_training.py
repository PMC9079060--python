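import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sinuseg._nn import sigmoid64
from sinuseg.errors import ConfigError, GeometryError, ShapeError, TrainingError
from sinuseg.phantoms import PhantomSpec, generate_dataset
from sinuseg.training import (
    AugmentParams,
    TrainConfig,
    augment,
    make_coarse_and_fine_training_pairs,
    train,
    weighted_bce,
    weighted_bce_with_logits,
)
from sinuseg.unet3d import NetworkSpec, build_network

LN2 = float(np.log(2.0))


def bce_loop(p, y, w):
    """Brute-force per-voxel evaluation of the weighted BCE."""
    total = 0.0
    for pi, yi in zip(np.ravel(p), np.ravel(y)):
        pi = min(max(pi, 1e-7), 1 - 1e-7)
        total += -(w * yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
    return total / np.size(p)


class TestWeightedBce:
    def test_perfect_prediction_is_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert weighted_bce(y, y, 1.0) < 1e-6

    def test_single_voxel_closed_form(self):
        assert abs(weighted_bce(np.array([0.5]), np.array([1.0]), 1.0) - LN2) < 1e-9

    def test_two_voxel_weighted_closed_form(self):
        loss = weighted_bce(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 2.0)
        assert abs(loss - 1.5 * LN2) < 1e-9

    def test_matches_per_voxel_loop(self, rng):
        for w in (1.0, 3.5):
            p = rng.uniform(0.01, 0.99, (4, 4, 4))
            y = (rng.uniform(size=(4, 4, 4)) < 0.5).astype(float)
            assert abs(weighted_bce(p, y, w) - bce_loop(p, y, w)) < 1e-12

    def test_permutation_invariant(self, rng):
        p = rng.uniform(0.01, 0.99, 64)
        y = (rng.uniform(size=64) < 0.4).astype(float)
        perm = rng.permutation(64)
        assert abs(weighted_bce(p, y, 2.0) - weighted_bce(p[perm], y[perm], 2.0)) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            weighted_bce(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_logits_equivalent(self, seed, w):
        r = np.random.default_rng(seed)
        z = r.normal(0, 3, 16)
        y = (r.uniform(size=16) < 0.5).astype(float)
        l_logits, _ = weighted_bce_with_logits(z, y, w)
        l_probs = weighted_bce(sigmoid64(z), y, w)
        assert l_logits >= 0
        assert abs(l_logits - l_probs) < 1e-9

    def test_logits_gradient_matches_fd(self, rng):
        z = rng.normal(0, 2, 27)
        y = (rng.uniform(size=27) < 0.5).astype(float)
        _, g = weighted_bce_with_logits(z, y, 2.5)
        for i in (0, 13, 26):
            eps = 1e-6
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (weighted_bce_with_logits(zp, y, 2.5)[0] - weighted_bce_with_logits(zm, y, 2.5)[0]) / (2 * eps)
            assert abs(fd - g[i]) < 1e-6


class TestAugment:
    def test_identity_params_exact(self, noisy_phantom):
        img, msk = noisy_phantom.volume.voxels, noisy_phantom.truth.voxels
        out_img, out_msk = augment(img, msk, params=AugmentParams())
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_mask_stays_binary(self, noisy_phantom):
        _, out_msk = augment(noisy_phantom.volume.voxels, noisy_phantom.truth.voxels, seed=3)
        assert set(np.unique(out_msk)) <= {0, 1}

    def test_seeded_determinism(self, noisy_phantom):
        img, msk = noisy_phantom.volume.voxels, noisy_phantom.truth.voxels
        a = augment(img, msk, seed=11)
        b = augment(img, msk, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_transform_roughly_preserves_foreground(self, noisy_phantom):
        cfg = TrainConfig(rotation_deg=10, scale_range=(1.0, 1.0), elastic_sd_vox=0)
        _, out_msk = augment(noisy_phantom.volume.voxels, noisy_phantom.truth.voxels, cfg=cfg, seed=5)
        n0, n1 = noisy_phantom.truth.count(), out_msk.sum()
        assert 0.8 < n1 / n0 < 1.25

    def test_ranges_must_admit_identity(self):
        with pytest.raises(ConfigError):
            TrainConfig(scale_range=(1.1, 1.3))


class TestTrainingPairs:
    @pytest.fixture(scope="class")
    def samples(self):
        return generate_dataset(3, PhantomSpec(), seed=21)

    def test_coarse_shapes(self, samples):
        coarse, _ = make_coarse_and_fine_training_pairs(samples, (32, 32, 32), (32, 32, 32))
        assert len(coarse) == 3
        for x, y in coarse:
            assert x.shape == y.shape == (32, 32, 32)
            assert set(np.unique(y)) <= {0, 1}

    def test_foreground_only_patches(self, samples):
        _, fine = make_coarse_and_fine_training_pairs(
            samples, (32, 32, 32), (32, 32, 32), patches_per_sample=4, fg_fraction=1.0, seed=2
        )
        assert len(fine) == 12
        assert all(y.sum() > 0 for _, y in fine)

    def test_seeded_patch_determinism(self, samples):
        a = make_coarse_and_fine_training_pairs(samples, (32,) * 3, (32,) * 3, seed=5)
        b = make_coarse_and_fine_training_pairs(samples, (32,) * 3, (32,) * 3, seed=5)
        for (xa, ya), (xb, yb) in zip(a[1], b[1]):
            np.testing.assert_array_equal(xa, xb)
            np.testing.assert_array_equal(ya, yb)

    def test_patch_larger_than_volume(self, samples):
        with pytest.raises(GeometryError):
            make_coarse_and_fine_training_pairs(samples, (32,) * 3, (128,) * 3)


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def small_sets(self):
        """10 small phantoms at 32^3 (0.8 mm voxels, same physical anatomy)."""
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=0.8)
        samples = generate_dataset(10, spec, seed=13)
        pairs = [(np.clip((s.volume.voxels + 1000) / 2000, 0, 1).astype(np.float32),
                  s.truth.voxels) for s in samples]
        return pairs[:8], pairs[8:]

    def test_loss_decreases_and_reproducible(self, small_sets):
        tr, va = small_sets
        cfg = TrainConfig(max_epochs=8, patience=8, batch_size=2, seed=5)
        net1, h1 = train(build_network(NetworkSpec(base_channels=4), seed=1), tr, va, cfg)
        assert h1.train_loss[-1] < h1.train_loss[0]
        assert h1.best_epoch == int(np.argmin(h1.val_loss)) + 1
        _, h2 = train(build_network(NetworkSpec(base_channels=4), seed=1), tr, va, cfg)
        np.testing.assert_array_equal(h1.train_loss, h2.train_loss)
        np.testing.assert_array_equal(h1.val_loss, h2.val_loss)

    def test_patience_zero_stops_at_first_non_improvement(self, small_sets):
        tr, va = small_sets
        cfg = TrainConfig(max_epochs=30, patience=0, batch_size=2, seed=5)
        _, h = train(build_network(NetworkSpec(base_channels=2), seed=2), tr, va, cfg)
        v = h.val_loss
        assert h.stop_epoch == len(v)
        if h.stop_epoch < 30:  # stopped early: last epoch did not improve on the running best
            assert v[-1] >= min(v[:-1])
            for i in range(1, len(v) - 1):  # every earlier epoch improved
                assert v[i] < min(v[:i])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_network(NetworkSpec(base_channels=2), seed=0), [], [], TrainConfig())

    def test_history_csv(self, small_sets, tmp_path):
        tr, va = small_sets
        cfg = TrainConfig(max_epochs=2, batch_size=4, seed=1, augment=False)
        _, h = train(build_network(NetworkSpec(base_channels=2), seed=0), tr, va, cfg)
        h.to_csv(tmp_path / "h.csv")
        lines = (tmp_path / "h.csv").read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss"
        assert len(lines) == 1 + h.stop_epoch
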