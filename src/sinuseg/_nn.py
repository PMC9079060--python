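"""Minimal CPU neural-network engine for the 3D U-Nets.

Layers operate on float32 arrays shaped ``(B, C, D, H, W)`` and implement
explicit ``forward``/``backward`` passes; 3x3x3 convolutions run through
numba-jitted direct kernels (cache-blocked per z-slice) which is the only
compute-heavy primitive. Everything is deterministic: no threading, no
atomics, fixed reduction order.

This engine exists to run the segmentation networks on an ordinary CPU;
it is not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "GroupNorm",
    "ReLU",
    "MaxPool2",
    "TrilinearUp2",
    "Adam",
    "sigmoid64",
]


@njit(cache=True, fastmath=True, nogil=True)
def _conv3_fwd(xp, W, out):
    """Direct 3x3x3 'same' convolution. xp is the zero-padded input
    (B, C, D+2, H+2, W+2); out is (B, Co, D, H, W), overwritten."""
    B, C, Dp, Hp, Wp = xp.shape
    Co = W.shape[0]
    D, H, Wd = Dp - 2, Hp - 2, Wp - 2
    acc = np.empty((H, Wd), np.float32)
    for b in range(B):
        for z in range(D):
            for co in range(Co):
                for y in range(H):
                    for x in range(Wd):
                        acc[y, x] = 0.0
                for ci in range(C):
                    for kz in range(3):
                        for ky in range(3):
                            for kx in range(3):
                                w = W[co, ci, kz, ky, kx]
                                for y in range(H):
                                    for x in range(Wd):
                                        acc[y, x] += w * xp[b, ci, z + kz, y + ky, x + kx]
                for y in range(H):
                    for x in range(Wd):
                        out[b, co, z, y, x] = acc[y, x]


@njit(cache=True, fastmath=True, nogil=True)
def _conv3_grad_w(xp, gout, gW):
    """Weight gradient: gW[co,ci,kz,ky,kx] = sum_bzyx gout * shifted x."""
    B, C, Dp, Hp, Wp = xp.shape
    Co = gout.shape[1]
    D, H, Wd = Dp - 2, Hp - 2, Wp - 2
    gW[:] = 0.0
    for b in range(B):
        for z in range(D):
            for ci in range(C):
                for co in range(Co):
                    for kz in range(3):
                        for ky in range(3):
                            for kx in range(3):
                                s = np.float32(0.0)
                                for y in range(H):
                                    for x in range(Wd):
                                        s += gout[b, co, z, y, x] * xp[b, ci, z + kz, y + ky, x + kx]
                                gW[co, ci, kz, ky, kx] += s


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


def _im2col27(xp: np.ndarray) -> np.ndarray:
    """(B, C, D+2, H+2, W+2) padded input -> (27*C, B*D*H*W) column matrix,
    rows ordered kernel-offset-major, channel-minor."""
    B, C, Dp, Hp, Wp = xp.shape
    D, H, Wd = Dp - 2, Hp - 2, Wp - 2
    col = np.empty((27 * C, B * D * H * Wd), xp.dtype)
    r = 0
    for kz in range(3):
        for ky in range(3):
            for kx in range(3):
                sl = xp[:, :, kz : kz + D, ky : ky + H, kx : kx + Wd]
                col[r : r + C] = sl.transpose(1, 0, 2, 3, 4).reshape(C, -1)
                r += C
    return col


def _conv3_fwd_ref(xp: np.ndarray, W: np.ndarray, out: np.ndarray) -> None:
    """Pure-numpy (im2col + GEMM) convolution, any dtype; the BLAS path for
    small deep-level grids and the independent oracle for the jitted kernel."""
    B, Co = out.shape[0], out.shape[1]
    C = xp.shape[1]
    col = _im2col27(xp)
    W2 = np.ascontiguousarray(W.transpose(2, 3, 4, 1, 0).reshape(27 * C, Co))
    out[:] = (W2.T @ col).reshape(Co, B, *out.shape[2:]).transpose(1, 0, 2, 3, 4)


def _conv3_grad_w_ref(xp: np.ndarray, gout: np.ndarray, gW: np.ndarray) -> None:
    B, Co = gout.shape[0], gout.shape[1]
    C = xp.shape[1]
    col = _im2col27(xp)
    g2 = gout.transpose(1, 0, 2, 3, 4).reshape(Co, -1)
    gW2 = col @ g2.T  # (27*C, Co)
    gW[:] = gW2.reshape(3, 3, 3, C, Co).transpose(4, 3, 0, 1, 2)


class Conv3x3:
    """3x3x3 convolution, stride 1, 'same' zero padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # jitted direct kernel for large grids; BLAS-backed einsum for small
        # deep-level grids (and for the float64 reference path)
        fast = x.dtype == np.float32 and x[0, 0].size > 4096
        x = np.ascontiguousarray(x)
        if train:
            self._x = x
        B, C, D, H, Wd = x.shape
        out = np.empty((B, self.W.shape[0], D, H, Wd), x.dtype)
        if fast:
            _conv3_fwd(_pad1(x), self.W, out)
        else:
            _conv3_fwd_ref(_pad1(x), self.W.astype(x.dtype), out)
        out += self.b[None, :, None, None, None]
        return out

    def backward(self, g: np.ndarray):
        x = self._x
        fast = x.dtype == np.float32 and x[0, 0].size > 4096
        g = np.ascontiguousarray(g, dtype=x.dtype)
        gW = np.empty_like(self.W, dtype=x.dtype)
        # input gradient = 'same' conv of g with the spatially flipped,
        # channel-transposed kernel (exact adjoint of the forward pass)
        W_adj = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).astype(x.dtype)
        )
        gx = np.empty_like(x)
        if fast:
            _conv3_grad_w(_pad1(x), g, gW)
            _conv3_fwd(_pad1(g), W_adj, gx)
        else:
            _conv3_grad_w_ref(_pad1(x), g, gW)
            _conv3_fwd_ref(_pad1(g), W_adj, gx)
        gb = g.sum(axis=(0, 2, 3, 4))
        self._x = None
        return gx, [gW, gb]


class Conv1x1:
    """1x1x1 convolution (per-voxel linear map across channels)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None, zero_init: bool = False):
        if zero_init or rng is None:
            self.W = np.zeros((c_out, c_in), dtype=np.float32)
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        B, C = x.shape[:2]
        out = np.matmul(self.W.astype(x.dtype), x.reshape(B, C, -1))
        out += self.b[:, None].astype(x.dtype)
        return out.reshape(B, self.W.shape[0], *x.shape[2:])

    def backward(self, g: np.ndarray):
        x = self._x
        B, C = x.shape[:2]
        Co = self.W.shape[0]
        g2 = np.ascontiguousarray(g, dtype=x.dtype).reshape(B, Co, -1)
        x2 = x.reshape(B, C, -1)
        gW = np.matmul(g2, x2.transpose(0, 2, 1)).sum(axis=0)
        gb = g2.sum(axis=(0, 2)).astype(x.dtype)
        gx = np.matmul(self.W.T.astype(x.dtype), g2).reshape(x.shape)
        self._x = None
        return gx, [gW, gb]


class GroupNorm:
    """Group normalization over channel groups, batch-size independent."""

    def __init__(self, c: int, n_groups: int = 8, eps: float = 1e-5):
        g = min(n_groups, c)
        while c % g:
            g -= 1
        self.groups = g
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        G = self.groups
        xg = x.reshape(B, G, -1)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv).reshape(x.shape).astype(x.dtype)
        if train:
            self._cache = (xhat, inv.astype(x.dtype), x.shape)
        return xhat * self.gamma[None, :, None, None, None] + self.beta[None, :, None, None, None]

    def backward(self, g: np.ndarray):
        xhat, inv, shape = self._cache
        B, C, D, H, W = shape
        G = self.groups
        ggamma = (g * xhat).sum(axis=(0, 2, 3, 4)).astype(xhat.dtype)
        gbeta = g.sum(axis=(0, 2, 3, 4)).astype(xhat.dtype)
        gxhat = (g * self.gamma[None, :, None, None, None]).reshape(B, G, -1)
        xh = xhat.reshape(B, G, -1)
        n = gxhat.shape[2]
        s1 = gxhat.sum(axis=2, keepdims=True)
        s2 = (gxhat * xh).sum(axis=2, keepdims=True)
        gx = inv / n * (n * gxhat - s1 - xh * s2)
        self._cache = None
        return gx.reshape(shape).astype(xhat.dtype), [ggamma, gbeta]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray):
        gx = g * self._mask
        self._mask = None
        return gx, []


class MaxPool2:
    """2x2x2 max pooling, stride 2. Ties break toward the first window
    element (fixed, deterministic)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, D, H, W = x.shape
        win = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            B, C, D // 2, H // 2, W // 2, 8
        )
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (B, C, D, H, W)
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray):
        B, C, D, H, W = self._shape
        g8 = np.zeros((B, C, D // 2, H // 2, W // 2, 8), g.dtype)
        np.put_along_axis(g8, self._idx[..., None], g[..., None], axis=-1)
        g8 = g8.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.ascontiguousarray(g8).reshape(B, C, D, H, W)
        del self._idx
        return gx, []


def _up2_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) factor-2 linear interpolation matrix (edge-clamped,
    half-voxel aligned: output o samples input coordinate o/2 - 0.25)."""
    U = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        c = o / 2.0 - 0.25
        lo = int(np.floor(c))
        frac = c - lo
        for i, w in ((lo, 1.0 - frac), (lo + 1, frac)):
            U[o, min(max(i, 0), n - 1)] += w
    return U


class TrilinearUp2:
    """Separable trilinear x2 upsampling (adjoint used for the gradient)."""

    _cache: dict[int, np.ndarray] = {}

    def params(self):
        return []

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            cls._cache[n] = _up2_matrix(n)
        return cls._cache[n]

    def _apply(self, x: np.ndarray, transpose: bool) -> np.ndarray:
        dtype = x.dtype
        for ax in (2, 3, 4):
            n = x.shape[ax]
            U = self._mat(n // 2).T if transpose else self._mat(n)
            x = np.moveaxis(np.tensordot(U.astype(dtype), x, axes=(1, ax)), 0, ax)
        return np.ascontiguousarray(x, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self._apply(x, transpose=False)

    def backward(self, g: np.ndarray):
        return self._apply(g, transpose=True), []


class Adam:
    """ADAM optimizer (beta1 0.9, beta2 0.999, eps 1e-8) over a flat
    parameter list; updates are in-place and deterministic."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = float(lr)
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g64 = g.astype(np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g64
            v *= self.beta2
            v += (1 - self.beta2) * g64 * g64
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p -= update.astype(p.dtype)


def sigmoid64(z: np.ndarray) -> np.ndarray:
    """Numerically safe logistic in float64; output in the open (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, 1e-12, 1.0 - 1e-12)
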