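"""Training engine: weighted binary cross-entropy, spatial augmentation,
coarse/fine dataset construction, and the ADAM + early-stopping loop.

The loss is the voxel-wise binary cross-entropy with a multiplicative
weight ``w`` on the positive-class term,

    L = -mean_n [ w * y_n * log(p_n) + (1 - y_n) * log(1 - p_n) ],

which counteracts the strong class imbalance of a small sinus inside a
large volume. By default ``w`` is the negative/positive voxel ratio of
each batch, capped at 100 so nearly-empty patches cannot blow it up.

Early stopping monitors the (unweighted) validation loss: training halts
once the validation loss has failed to improve for ``patience``
consecutive epochs, and the returned weights are those of the best
validation epoch. Everything is reproducible from ``TrainConfig.seed``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError, ShapeError, TrainingError
from .phantoms import PhantomSample
from .unet3d import UNet3D, normalize_hu
from ._nn import sigmoid64
from .volume_io import BinaryMask, Volume, resample_to_shape

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "weighted_bce",
    "weighted_bce_with_logits",
    "AugmentParams",
    "sample_augment_params",
    "augment",
    "make_coarse_and_fine_training_pairs",
    "train",
]

log = logging.getLogger(__name__)

EPS = 1e-7  # probability clamp before logs


@dataclass
class TrainConfig:
    learning_rate: float = 1.25e-4
    max_epochs: int = 40
    batch_size: int = 2
    patience: int = 5
    pos_weight: float | None = None  # None -> per-batch neg/pos, capped
    pos_weight_cap: float = 100.0
    augment: bool = True
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_grid: int = 4
    elastic_sd_vox: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.patience < 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigError("patience >= 0, max_epochs >= 1, batch_size >= 1 required")
        lo, hi = self.scale_range
        if not (self.rotation_deg >= 0 and lo <= 1.0 <= hi and self.elastic_sd_vox >= 0):
            raise ConfigError("augmentation ranges must admit the identity transform")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for i, (t, v) in enumerate(zip(self.train_loss, self.val_loss), start=1):
                w.writerow([i, f"{t:.8f}", f"{v:.8f}"])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def weighted_bce(p: np.ndarray, y: np.ndarray, w: float = 1.0) -> float:
    """Positive-class-weighted binary cross-entropy over all voxels.

    ``p`` is clamped to ``[1e-7, 1 - 1e-7]`` before the logarithms; the
    result is non-negative for any ``w >= 0``.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if w < 0:
        raise ValueError("w must be >= 0")
    pc = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(w * y * np.log(pc) + (1.0 - y) * np.log1p(-pc)))


def weighted_bce_with_logits(z: np.ndarray, y: np.ndarray, w: float = 1.0):
    """Same loss evaluated from logits (numerically stable), plus its
    gradient with respect to the logits. Equals ``weighted_bce(sigmoid(z),
    y, w)`` away from the clamp."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if z.shape != y.shape:
        raise ShapeError(f"shape mismatch: z {z.shape} vs y {y.shape}")
    # softplus(z) = log(1 + e^z), computed stably
    sp_pos = np.logaddexp(0.0, -z)  # softplus(-z)
    sp_neg = np.logaddexp(0.0, z)   # softplus(z)
    loss = float(np.mean(w * y * sp_pos + (1.0 - y) * sp_neg))
    p = sigmoid64(z)
    grad = (w * y * (p - 1.0) + (1.0 - y) * p) / z.size
    return loss, grad.astype(np.float32)


def _batch_pos_weight(y: np.ndarray, cfg: TrainConfig) -> float:
    if cfg.pos_weight is not None:
        return float(cfg.pos_weight)
    pos = float(y.sum())
    if pos == 0:
        return 1.0
    return float(min(cfg.pos_weight_cap, (y.size - pos) / pos))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentParams:
    """One sampled spatial transform: rotation (deg, about the three grid
    axes), isotropic scale, and an elastic displacement field (voxels)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    elastic: np.ndarray | None = None  # (3, *grid) displacement, voxels

    @property
    def is_identity(self) -> bool:
        return (
            all(r == 0 for r in self.rotation_deg)
            and self.scale == 1.0
            and (self.elastic is None or not np.any(self.elastic))
        )


def sample_augment_params(shape, cfg: TrainConfig, rng: np.random.Generator) -> AugmentParams:
    rot = tuple(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg) for _ in range(3))
    scale = float(rng.uniform(*cfg.scale_range))
    elastic = None
    if cfg.elastic_sd_vox > 0 and cfg.elastic_grid >= 2:
        coarse = rng.normal(0.0, cfg.elastic_sd_vox, size=(3, *([cfg.elastic_grid] * 3)))
        elastic = np.stack(
            [ndimage.zoom(coarse[a], [s / cfg.elastic_grid for s in shape], order=1) for a in range(3)]
        )
    return AugmentParams(rot, scale, elastic)


def _rot_matrix(deg) -> np.ndarray:
    a, b, c = np.deg2rad(deg)
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    r0 = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    r1 = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    r2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return r0 @ r1 @ r2


def augment(
    image: np.ndarray | Volume,
    mask: np.ndarray | BinaryMask,
    params: AugmentParams | None = None,
    cfg: TrainConfig | None = None,
    seed: int | np.random.Generator | None = None,
):
    """Apply one random (or given) spatial transform to an image/mask pair.

    The same warp is applied to both: linear interpolation for the image,
    nearest-neighbour for the mask so it stays binary. Identity parameters
    return the inputs unchanged, bit for bit.
    """
    img_arr = image.voxels if isinstance(image, Volume) else np.asarray(image)
    msk_arr = mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if img_arr.shape != msk_arr.shape:
        raise ShapeError("image and mask shapes differ")
    if params is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        params = sample_augment_params(img_arr.shape, cfg or TrainConfig(), rng)
    if params.is_identity:
        out_img, out_msk = img_arr.copy(), msk_arr.copy()
    else:
        center = (np.asarray(img_arr.shape) - 1) / 2.0
        idx = np.indices(img_arr.shape, dtype=np.float64)
        rel = idx - center[:, None, None, None]
        # inverse map: output voxel -> input coordinate
        R = _rot_matrix(params.rotation_deg)
        inv = R.T / params.scale
        src = np.einsum("ab,b...->a...", inv, rel) + center[:, None, None, None]
        if params.elastic is not None:
            src = src + params.elastic
        out_img = ndimage.map_coordinates(img_arr, src, order=1, mode="nearest").astype(img_arr.dtype)
        out_msk = ndimage.map_coordinates(msk_arr, src, order=0, mode="nearest").astype(msk_arr.dtype)
    if isinstance(image, Volume):
        out_img = Volume(out_img, image.spacing, image.origin)
    if isinstance(mask, BinaryMask):
        out_msk = BinaryMask(out_msk, mask.spacing, mask.origin)
    return out_img, out_msk


# ---------------------------------------------------------------------------
# dataset construction for the two stages
# ---------------------------------------------------------------------------

def make_coarse_and_fine_training_pairs(
    samples: list[PhantomSample],
    fixed_size: tuple[int, int, int] = (32, 32, 32),
    patch_size: tuple[int, int, int] = (32, 32, 32),
    patches_per_sample: int = 2,
    fg_fraction: float = 1.0,
    seed: int = 0,
    bg_patches_per_sample: float = 0.0,
):
    """Build the two training datasets from full-resolution samples.

    Coarse pairs: each volume downsampled to ``fixed_size`` (linear) with
    its mask (nearest-neighbour). Fine pairs: ``patches_per_sample``
    full-resolution patches per sample; a fraction ``fg_fraction`` of them
    is drawn from origins whose patch contains at least one positive voxel
    (1.0 = foreground-only sampling), the rest uniformly. On top of that,
    ``bg_patches_per_sample`` (may be fractional; accumulated across
    samples) uniform-origin patches are added per sample regardless of
    content, so the patch network also sees sinus-free anatomy — e.g. the
    nasal airway — that a loose proposal stage may hand it at inference.

    Inputs are HU-window normalized; targets stay {0, 1}. Returns
    ``(coarse_pairs, fine_pairs)`` as lists of (x, y) arrays.
    """
    fixed_size = tuple(int(s) for s in fixed_size)
    patch_size = tuple(int(s) for s in patch_size)
    rng = np.random.default_rng(seed)
    coarse, fine = [], []
    bg_budget = 0.0
    for sample in samples:
        vol, msk = sample.volume, sample.truth
        if any(p > s for p, s in zip(patch_size, vol.shape)):
            raise GeometryError(f"patch {patch_size} larger than volume {vol.shape}")
        cv = resample_to_shape(vol, fixed_size)
        cm = resample_to_shape(msk, fixed_size)
        coarse.append((normalize_hu(cv.voxels), cm.voxels.astype(np.uint8)))

        x = normalize_hu(vol.voxels)
        y = msk.voxels
        fg = np.argwhere(y > 0)
        max_origin = np.asarray(vol.shape) - np.asarray(patch_size)
        for _ in range(patches_per_sample):
            if len(fg) and rng.uniform() < fg_fraction:
                # centre a patch near a random foreground voxel, clipped inside
                c = fg[rng.integers(len(fg))]
                lo = c - np.asarray(patch_size) // 2
                # jitter so patches are not always centred
                lo = lo + rng.integers(-4, 5, size=3)
            else:
                lo = rng.integers(0, max_origin + 1)
            lo = np.clip(lo, 0, max_origin)
            sl = tuple(slice(int(o), int(o) + p) for o, p in zip(lo, patch_size))
            if len(fg) and fg_fraction >= 1.0 and y[sl].sum() == 0:
                # guaranteed-foreground mode: recentre exactly on the voxel
                lo = np.clip(c - np.asarray(patch_size) // 2, 0, max_origin)
                sl = tuple(slice(int(o), int(o) + p) for o, p in zip(lo, patch_size))
            fine.append((x[sl].copy(), y[sl].copy()))
        bg_budget += bg_patches_per_sample
        while bg_budget >= 1.0:
            bg_budget -= 1.0
            lo = rng.integers(0, max_origin + 1)
            sl = tuple(slice(int(o), int(o) + p) for o, p in zip(lo, patch_size))
            fine.append((x[sl].copy(), y[sl].copy()))
    return coarse, fine


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _dataset_loss(net: UNet3D, pairs, batch_size: int) -> float:
    """Unweighted BCE over a dataset, evaluation mode."""
    total, n = 0.0, 0
    for i in range(0, len(pairs), batch_size):
        xb = np.stack([p[0] for p in pairs[i : i + batch_size]])[:, None]
        yb = np.stack([p[1] for p in pairs[i : i + batch_size]])[:, None]
        z = net.forward_logits(xb, train=False)
        loss, _ = weighted_bce_with_logits(z, yb, w=1.0)
        total += loss * xb.shape[0]
        n += xb.shape[0]
    return total / n


def train(
    net: UNet3D,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[UNet3D, TrainHistory]:
    """Train ``net`` in place with ADAM and validation-based early stopping.

    ``train_set``/``val_set`` are lists of (normalized image, {0,1} mask)
    array pairs whose spatial dimensions are divisible by the network's
    downsampling factor. Stops after ``cfg.patience`` consecutive epochs
    without validation improvement (patience 0: the first such epoch) or at
    ``cfg.max_epochs``; the best-epoch weights are restored before return.
    """
    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = net.make_optimizer(cfg.learning_rate)
    params = net.parameters()
    history = TrainHistory()
    best = np.inf
    best_state = [p.copy() for p in params]
    bad = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_set[j] for j in order[i : i + cfg.batch_size]]
            xs, ys = [], []
            for x, y in batch:
                if cfg.augment:
                    x, y = augment(x, y, cfg=cfg, seed=rng)
                xs.append(x)
                ys.append(y)
            xb = np.stack(xs)[:, None]
            yb = np.stack(ys)[:, None]
            z = net.forward_logits(xb, train=True)
            w = _batch_pos_weight(yb, cfg)
            loss, dz = weighted_bce_with_logits(z, yb, w)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            grads = net.backward(dz)
            opt.step(grads)
            epoch_loss += loss * xb.shape[0]
            seen += xb.shape[0]
        history.train_loss.append(epoch_loss / seen)
        val_loss = _dataset_loss(net, val_set, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.val_loss.append(val_loss)
        history.stop_epoch = epoch
        log.info("epoch %d: train_loss %.6f val_loss %.6f", epoch, history.train_loss[-1], val_loss)
        if val_loss < best:
            best = val_loss
            history.best_epoch = epoch
            best_state = [p.copy() for p in params]
            bad = 0
        else:
            bad += 1
            if bad > cfg.patience:
                break
    for p, b in zip(params, best_state):
        p[...] = b
    return net, history
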