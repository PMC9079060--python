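"""3D U-Net for binary volumetric segmentation.

Architecture (both pipeline stages use one instance each, with
independent weights): ``n_encoders`` encoder blocks and
``n_encoders - 1`` decoder blocks; each block is ``convs_per_block``
3x3x3 convolutions, each followed by group normalization (8 groups) and
ReLU. A 2x2x2 max pool (stride 2) sits between encoder levels, so the
spatial resolution halves ``n_decoders`` times; the decoder path restores
it with trilinear upsampling and channel-concatenated skip connections.
The head is a single 1x1x1 convolution through a logistic squashing, so
the network is a per-voxel binary classifier.

Channel widths per level are ``base_channels * (1, 2, 4, ...)``. The head
is zero-initialized: an untrained network outputs the logistic midpoint
0.5 everywhere, and training grows the decision function from there.

Inputs are HU volumes mapped through a fixed intensity window to [0, 1]
(:func:`normalize_hu`), which keeps inference deterministic across scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import Adam, Conv1x1, Conv3x3, GroupNorm, MaxPool2, ReLU, TrilinearUp2, sigmoid64
from .errors import ConfigError, ShapeError

__all__ = ["NetworkSpec", "UNet3D", "build_network", "normalize_hu", "HU_WINDOW"]

HU_WINDOW = (-1000.0, 1000.0)


def normalize_hu(voxels: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    """Linearly map a fixed HU window to [0, 1], clipping outside it."""
    lo, hi = window
    return ((np.clip(voxels, lo, hi) - lo) / (hi - lo)).astype(np.float32)


@dataclass(frozen=True)
class NetworkSpec:
    n_encoders: int = 4
    n_decoders: int = 3
    convs_per_block: int = 2
    base_channels: int = 8
    n_groups: int = 8
    # initial bias of the zero-initialized head: 0 starts the output at the
    # logistic midpoint 0.5; a positive value starts training from an
    # over-inclusive prior (the decision surface then shrinks toward the
    # true boundary instead of having to cross the threshold from below)
    head_bias_init: float = 0.0

    def __post_init__(self) -> None:
        if self.n_decoders != self.n_encoders - 1:
            raise ConfigError("n_decoders must equal n_encoders - 1")
        if self.n_encoders < 2 or self.convs_per_block < 1 or self.base_channels < 1:
            raise ConfigError(f"invalid network spec: {self}")

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.n_decoders

    def channels(self, level: int) -> int:
        return self.base_channels * (2 ** level)


class _Block:
    """convs_per_block x (Conv3x3 -> GroupNorm -> ReLU)."""

    def __init__(self, c_in: int, c_out: int, n_convs: int, n_groups: int, rng):
        self.layers = []
        c = c_in
        for _ in range(n_convs):
            self.layers += [Conv3x3(c, c_out, rng), GroupNorm(c_out, n_groups), ReLU()]
            c = c_out

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        grads = []
        for l in reversed(self.layers):
            g, gp = l.backward(g)
            grads = gp + grads
        return g, grads


class UNet3D:
    """A seeded, deterministic 3D U-Net. See the module docstring."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        self.spec = spec if spec is not None else NetworkSpec()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        s = self.spec
        self.enc = []
        c_in = 1
        for lvl in range(s.n_encoders):
            self.enc.append(_Block(c_in, s.channels(lvl), s.convs_per_block, s.n_groups, rng))
            c_in = s.channels(lvl)
        self.pools = [MaxPool2() for _ in range(s.n_decoders)]
        self.ups = [TrilinearUp2() for _ in range(s.n_decoders)]
        self.dec = []
        for lvl in range(s.n_decoders - 1, -1, -1):  # deepest decoder first
            c_cat = s.channels(lvl + 1) + s.channels(lvl)
            self.dec.append(_Block(c_cat, s.channels(lvl), s.convs_per_block, s.n_groups, rng))
        self.head = Conv1x1(s.channels(0), 1, rng=None, zero_init=True)
        self.head.b[:] = np.float32(s.head_bias_init)
        self._modules = [*self.enc, *self.dec, self.head]
        self._skip_channels = [s.channels(lvl + 1) for lvl in range(s.n_decoders - 1, -1, -1)]

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for m in self._modules for p in m.params()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return self.parameters()

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.dtype != np.float64:  # float64 runs the reference (oracle) path
            x = x.astype(np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.ndim != 5 or x.shape[1] != 1:
            raise ShapeError(f"expected (B, 1, D, H, W) or (D, H, W) input, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ShapeError("network input contains non-finite voxels")
        f = self.spec.downsample_factor
        for d in x.shape[2:]:
            if d % f or d < f:
                raise ShapeError(
                    f"each spatial dimension must be a multiple of {f} (and >= {f}); got {x.shape[2:]}"
                )
        return np.ascontiguousarray(x)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h, train)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for j, block in enumerate(self.dec):
            h = self.ups[j].forward(h, train)
            skip = skips[len(skips) - 1 - j]
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, g_logits: np.ndarray) -> list[np.ndarray]:
        """Gradient of a scalar loss wrt all parameters, given the loss
        gradient wrt the head logits. Must follow forward_logits(train=True)."""
        grads: dict[int, list[np.ndarray]] = {}
        g, gp = self.head.backward(np.ascontiguousarray(g_logits, dtype=np.float32))
        grads[id(self.head)] = gp
        n_dec = len(self.dec)
        skip_grads: list[np.ndarray | None] = [None] * n_dec
        # decoders ran in order dec[0] (deepest) .. dec[-1]; reverse them
        for j in range(n_dec - 1, -1, -1):
            block = self.dec[j]
            g, gp = block.backward(g)
            grads[id(block)] = gp
            c_up = self._skip_channels[j]
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            skip_grads[n_dec - 1 - j] = np.ascontiguousarray(g_skip)  # encoder level
            g, _ = self.ups[j].backward(np.ascontiguousarray(g_up))
        # g is now the gradient wrt the deepest encoder block's output
        g, gp = self.enc[-1].backward(g)
        grads[id(self.enc[-1])] = gp
        for i in range(len(self.enc) - 2, -1, -1):
            g, _ = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g, gp = self.enc[i].backward(g)
            grads[id(self.enc[i])] = gp
        return [gr for m in self._modules for gr in grads[id(m)]]

    # -- inference ----------------------------------------------------------

    def predict(self, voxels: np.ndarray) -> np.ndarray:
        """Probability map for one 3D grid of window-normalized intensities.

        Evaluation mode; repeated calls are bit-identical. Output is float64
        strictly inside (0, 1), same spatial shape as the input.
        """
        z = self.forward_logits(voxels, train=False)
        p = sigmoid64(z[0, 0] if np.asarray(voxels).ndim == 3 else z)
        return np.clip(p, 1e-7, 1.0 - 1e-7)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.parameters(), lr)

    # -- checkpoints --------------------------------------------------------

    def save(self, path, history: dict | None = None) -> None:
        meta = {"spec": asdict(self.spec), "seed": self.seed, "history": history or {}}
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, expect_spec: NetworkSpec | None = None) -> "UNet3D":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = NetworkSpec(**meta["spec"])
            if expect_spec is not None and spec != expect_spec:
                raise ConfigError(
                    f"checkpoint spec {spec} does not match requested {expect_spec}"
                )
            net = cls(spec, seed=meta["seed"])
            params = net.parameters()
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.shape:
                    raise ConfigError(f"checkpoint parameter {i} has shape {arr.shape}, expected {p.shape}")
                p[...] = arr
            net.history = meta.get("history", {})
        return net


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> UNet3D:
    """Construct a seeded 3D U-Net; two builds with the same spec and seed
    produce identical parameters and therefore identical outputs."""
    return UNet3D(spec, seed)
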