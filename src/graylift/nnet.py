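"""Minimal NumPy convolutional-network toolkit with hand-written backprop.

Only what the codec's predictor needs: 2-D convolutions (kernel 1 or 3,
stride 1 or 2, zero 'same' padding), ReLU, nearest-neighbour ×2 upsampling,
residual blocks, mirror padding with an exact adjoint, and Adam.

Everything runs in a single dtype (float32 by default) with plain NumPy
ops, so two forward passes over the same arrays are bit-identical — the
property the lossless codec relies on at decode time. Gradients are exact
(finite-difference-checked in the test suite), not autograd-derived.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ReLU",
    "NearestUp2",
    "ResBlock",
    "Adam",
    "mirror_pad2d",
    "mirror_pad2d_backward",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)


class Module:
    """Base class: a flat, ordered parameter list plus forward/backward."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0


class Conv2d(Module):
    """2-D convolution with zero 'same' padding; kernel ∈ {1, 3}, stride ∈ {1, 2}."""

    def __init__(
        self,
        cin: int,
        cout: int,
        ksize: int = 3,
        stride: int = 1,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "conv",
    ):
        if ksize not in (1, 3) or stride not in (1, 2):
            raise InvalidInputError("Conv2d supports ksize in {1,3}, stride in {1,2}")
        self.cin, self.cout, self.ksize, self.stride = cin, cout, ksize, stride
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        w = (rng.standard_normal((cout, cin, ksize, ksize)) * std).astype(dtype)
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise InvalidInputError(f"expected {self.cin} input channels, got {c}")
        k, s, p = self.ksize, self.stride, self.ksize // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        out = np.empty((n, self.cout, oh, ow), dtype=x.dtype)
        out[...] = self.b.data[None, :, None, None]
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + s * oh : s, dj : dj + s * ow : s]
                w2 = self.W.data[:, :, di, dj]
                out += np.matmul(w2[None], xs.reshape(n, c, oh * ow)).reshape(
                    n, self.cout, oh, ow
                )
        self._cache = ((n, c, h, w), xp, (oh, ow))
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (n, c, h, w), xp, (oh, ow) = self._cache
        k, s, p = self.ksize, self.stride, self.ksize // 2
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gyf = gy.reshape(n, self.cout, oh * ow)
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + s * oh : s, dj : dj + s * ow : s]
                self.W.grad[:, :, di, dj] += np.matmul(
                    gyf, xs.reshape(n, c, oh * ow).transpose(0, 2, 1)
                ).sum(axis=0)
                gxp[:, :, di : di + s * oh : s, dj : dj + s * ow : s] += np.matmul(
                    self.W.data[:, :, di, dj].T[None], gyf
                ).reshape(n, c, oh, ow)
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.zeros((), dtype=x.dtype))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, np.zeros((), dtype=gy.dtype))


class NearestUp2(Module):
    """Nearest-neighbour ×2 upsampling; adjoint is 2×2 block summation."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = gy.shape
        return gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class ResBlock(Module):
    """conv3-ReLU-conv3 with an additive skip, then ReLU.

    When the channel count changes, the skip path is a learned 1×1
    projection; otherwise it is the identity.
    """

    def __init__(self, cin: int, cout: int, *, rng, dtype=np.float32, name="res"):
        self.conv1 = Conv2d(cin, cout, 3, rng=rng, dtype=dtype, name=f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, dtype=dtype, name=f"{name}.conv2")
        self.proj = (
            None
            if cin == cout
            else Conv2d(cin, cout, 1, rng=rng, dtype=dtype, name=f"{name}.proj")
        )
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = x if self.proj is None else self.proj.forward(x)
        return self.relu2.forward(h + skip)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(gy)
        gx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        gx_skip = g if self.proj is None else self.proj.backward(g)
        return gx_main + gx_skip


class Adam(Module):
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self._params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self._params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (lr / c1) * m / (np.sqrt(v / c2) + self.eps)


def _mirror_indices(n: int, lo: int, hi: int) -> np.ndarray:
    """Source indices for mirror (reflect) padding of a length-n axis.

    Works for arbitrary pad widths by folding with period ``2n - 2``;
    degenerates to edge replication when ``n == 1``.
    """
    if n == 1:
        return np.zeros(n + lo + hi, dtype=np.intp)
    idx = np.arange(-lo, n + hi)
    period = 2 * n - 2
    pos = np.mod(idx, period)
    return np.where(pos < n, pos, period - pos).astype(np.intp)


def mirror_pad2d(x: np.ndarray, pad_h: int, pad_w: int):
    """Mirror-pad the trailing two axes; returns (padded, index pair)."""
    n, c, h, w = x.shape
    ri = _mirror_indices(h, 0, pad_h)
    ci = _mirror_indices(w, 0, pad_w)
    return x[:, :, ri[:, None], ci[None, :]], (ri, ci)


def mirror_pad2d_backward(gy: np.ndarray, shape_hw: tuple[int, int], idx) -> np.ndarray:
    """Exact adjoint of :func:`mirror_pad2d` (scatter-add over mirrored cells)."""
    ri, ci = idx
    h, w = shape_hw
    n, c = gy.shape[:2]
    tmp = np.zeros((h, n, c, gy.shape[3]), dtype=gy.dtype)
    np.add.at(tmp, ri, gy.transpose(2, 0, 1, 3))
    out = np.zeros((w, n, c, h), dtype=gy.dtype)
    np.add.at(out, ci, tmp.transpose(3, 1, 2, 0))
    return out.transpose(1, 2, 3, 0)
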