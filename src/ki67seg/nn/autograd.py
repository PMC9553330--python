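"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the segmentation network needs: 2D
convolution (arbitrary stride/dilation), adaptive average pooling, 2x2 max
pooling, bilinear resampling, SeLU/sigmoid/ReLU, elementwise arithmetic
with broadcasting, channel concatenation, and reductions.  Tensors form a
DAG; ``Tensor.backward()`` runs reverse topological accumulation.

All data is float32; gradients are float32.  This is deliberately a small
engine, not a framework: no graphs-of-graphs, no in-place ops, no views.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]

# SeLU constants (Klambauer et al. self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._prev = tuple(prev)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._prev)

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        break
                else:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g / n, self.data.shape).copy())
        return out

    # -- activations ------------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def selu(self):
        pos = self.data > 0
        expx = np.exp(np.minimum(self.data, 0.0))
        val = _SELU_SCALE * np.where(pos, self.data, _SELU_ALPHA * (expx - 1.0))
        out = Tensor(val, (self,))

        def backward(g):
            self._accum(g * _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * expx))

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- spatial ops (NCHW) ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, dilation: int = 1) -> "Tensor":
        """'same'-padded (for stride 1) k x k convolution, NCHW layout.

        weight: (Cout, Cin, k, k).  For stride s the output is H//s x W//s.
        Implemented as a sum of k*k shifted 1x1 contractions (tensordot →
        BLAS), which is fast for the small kernels used here.
        """
        x, w = self.data, weight.data
        n, cin, h, wd = x.shape
        cout, cin2, k, _ = w.shape
        assert cin == cin2, "channel mismatch in conv2d"
        pad = dilation * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        oh, ow = h // stride, wd // stride
        out_data = np.zeros((n, cout, oh, ow), dtype=np.float32)
        slices = []
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i * dilation : i * dilation + h : stride,
                        j * dilation : j * dilation + wd : stride]
                slices.append(sl)
                # (N,Ci,oh,ow) x (Cout,Ci) -> (N,oh,ow,Cout)
                out_data += np.moveaxis(
                    np.tensordot(sl, w[:, :, i, j], axes=([1], [1])), 3, 1
                )
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        prev = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_data, prev)

        def backward(g):
            if weight.requires_grad:
                gw = np.empty_like(w)
                for idx, sl in enumerate(slices):
                    i, j = divmod(idx, k)
                    gw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros(
                    (n, cin, h + 2 * pad, wd + 2 * pad), dtype=np.float32
                )
                for idx in range(k * k):
                    i, j = divmod(idx, k)
                    gi = np.moveaxis(
                        np.tensordot(g, w[:, :, i, j], axes=([1], [0])), 3, 1
                    )
                    gxp[:, :, i * dilation : i * dilation + h : stride,
                        j * dilation : j * dilation + wd : stride] += gi
                self._accum(gxp[:, :, pad : pad + h, pad : pad + wd] if pad else gxp)

        out._backward = backward
        return out

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling with stride 2 (spatial dims must be even)."""
        n, c, h, w = self.data.shape
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        arg = xf.argmax(axis=-1)
        out = Tensor(np.take_along_axis(xf, arg[..., None], axis=-1)[..., 0], (self,))

        def backward(g):
            gf = np.zeros_like(xf)
            np.put_along_axis(gf, arg[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n, c, h, w))

        out._backward = backward
        return out

    def avgpool_to(self, size: int) -> "Tensor":
        """Adaptive mean pooling to a size x size grid (dims must divide)."""
        n, c, h, w = self.data.shape
        assert h % size == 0 and w % size == 0, "avgpool_to requires divisible dims"
        bh, bw = h // size, w // size
        out = Tensor(
            self.data.reshape(n, c, size, bh, size, bw).mean(axis=(3, 5)), (self,)
        )

        def backward(g):
            gx = np.broadcast_to(
                g[:, :, :, None, :, None] / (bh * bw), (n, c, size, bh, size, bw)
            )
            self._accum(gx.reshape(n, c, h, w).copy())

        out._backward = backward
        return out

    def maxpool_to(self, size: int) -> "Tensor":
        """Adaptive max pooling to a size x size grid (dims must divide)."""
        n, c, h, w = self.data.shape
        assert h % size == 0 and w % size == 0
        bh, bw = h // size, w // size
        xf = self.data.reshape(n, c, size, bh, size, bw).transpose(0, 1, 2, 4, 3, 5)
        xf = xf.reshape(n, c, size, size, bh * bw)
        arg = xf.argmax(axis=-1)
        out = Tensor(np.take_along_axis(xf, arg[..., None], axis=-1)[..., 0], (self,))

        def backward(g):
            gf = np.zeros_like(xf)
            np.put_along_axis(gf, arg[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, size, size, bh, bw).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n, c, h, w))

        out._backward = backward
        return out

    def bilinear_resize(self, out_h: int, out_w: int) -> "Tensor":
        """Bilinear resampling to (out_h, out_w), half-pixel-centre convention."""
        _, _, h, w = self.data.shape
        ah = _bilinear_matrix(out_h, h)
        aw = _bilinear_matrix(out_w, w)
        # out[n,c,a,b] = sum_{h,w} Ah[a,h] Aw[b,w] x[n,c,h,w]
        tmp = np.tensordot(self.data, ah, axes=([2], [1]))  # (N,C,W,OH)
        out_data = np.tensordot(tmp, aw, axes=([2], [1]))  # (N,C,OH,OW)
        out = Tensor(out_data, (self,))

        def backward(g):
            t = np.tensordot(g, aw, axes=([3], [0]))  # (N,C,OH,W)
            self._accum(
                np.tensordot(t, ah, axes=([2], [0])).transpose(0, 1, 3, 2)
            )

        out._backward = backward
        return out

    def concat_channels(self, *others: "Tensor") -> "Tensor":
        parts = (self,) + others
        out = Tensor(np.concatenate([p.data for p in parts], axis=1), parts)
        splits = np.cumsum([p.data.shape[1] for p in parts])[:-1]

        def backward(g):
            for part, gp in zip(parts, np.split(g, splits, axis=1)):
                part._accum(gp)

        out._backward = backward
        return out


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """(n_out, n_in) interpolation matrix; rows sum to 1 (constants preserved)."""
    key = (n_out, n_in)
    if key not in _BILINEAR_CACHE:
        a = np.zeros((n_out, n_in), dtype=np.float32)
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac[src < 0] = 0.0
        rows = np.arange(n_out)
        np.add.at(a, (rows, i0), (1.0 - frac).astype(np.float32))
        np.add.at(a, (rows, i1), frac.astype(np.float32))
        _BILINEAR_CACHE[key] = a
    return _BILINEAR_CACHE[key]


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
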