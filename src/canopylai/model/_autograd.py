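"""Minimal reverse-mode autodiff on numpy arrays.

Everything the regressors in this package need — broadcasting arithmetic,
matmul, elementwise nonlinearities, reductions, shape ops, 1-D/2-D
convolution via im2col, and max pooling — with float64 data throughout so
seeded training is bit-reproducible on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "conv2d", "maxpool1d", "maxpool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to the operand's shape."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_prev", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._prev = tuple(prev)
        self._backward = None

    # -- basics ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def _bw():
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def _bw():
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other**-1.0
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))

        def _bw():
            self.grad += out.grad * p * self.data ** (p - 1)

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def _bw():
            self.grad += _unbroadcast(
                out.grad @ other.data.swapaxes(-1, -2), self.data.shape
            )
            other.grad += _unbroadcast(
                self.data.swapaxes(-1, -2) @ out.grad, other.data.shape
            )

        out._backward = _bw
        return out

    # -- nonlinearities -------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def _bw():
            self.grad += out.grad * out.data

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def _bw():
            self.grad += out.grad / self.data

        out._backward = _bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))

        def _bw():
            self.grad += out.grad * (1.0 - out.data**2)

        out._backward = _bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))

        def _bw():
            self.grad += out.grad * out.data * (1.0 - out.data)

        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _bw():
            self.grad += out.grad * (self.data > 0)

        out._backward = _bw
        return out

    # -- reductions and shape ops --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def _bw():
            self.grad += out.grad.reshape(self.data.shape)

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def _bw():
            self.grad += out.grad.transpose(*inv)

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def _bw():
            np.add.at(self.grad, idx, out.grad)

        out._backward = _bw
        return out

    def softmax(self, axis=-1):
        """Softmax along an axis; the max shift is a constant (exact)."""
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- engine ---------------------------------------------------------
    def backward(self):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.data.ndim
            idx[axis] = slice(a, b)
            t.grad += out.grad[tuple(idx)]

    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution. x: (N, C, W); w: (Cout, C, k); b: (Cout,)."""
    n, c, width = x.data.shape
    cout, _, k = w.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,C,W,k)
    colsm = cols.transpose(0, 2, 1, 3).reshape(n, width, c * k)
    wm = w.data.reshape(cout, c * k)
    out_data = (colsm @ wm.T + b.data[None, None, :]).transpose(0, 2, 1)
    out = Tensor(out_data, (x, w, b))

    def _bw():
        go = out.grad.transpose(0, 2, 1)  # (N,W,Cout)
        w.grad += (go.reshape(-1, cout).T @ colsm.reshape(-1, c * k)).reshape(
            w.data.shape
        )
        b.grad += go.sum(axis=(0, 1))
        dcols = (go @ wm).reshape(n, width, c, k).transpose(0, 2, 1, 3)
        gxp = np.zeros_like(xp)
        for kk in range(k):
            gxp[:, :, kk : kk + width] += dcols[:, :, :, kk]
        x.grad += gxp[:, :, pad : pad + width]

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2-D convolution. x: (N,C,H,W); w: (Cout,C,kh,kw)."""
    n, c, h, width = x.data.shape
    cout, _, kh, kw = w.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    colsm = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * width, c * kh * kw)
    wm = w.data.reshape(cout, c * kh * kw)
    out_data = (colsm @ wm.T + b.data[None, None, :]).transpose(0, 2, 1)
    out = Tensor(out_data.reshape(n, cout, h, width), (x, w, b))

    def _bw():
        go = out.grad.reshape(n, cout, h * width).transpose(0, 2, 1)
        w.grad += (go.reshape(-1, cout).T @ colsm.reshape(-1, c * kh * kw)).reshape(
            w.data.shape
        )
        b.grad += go.sum(axis=(0, 1))
        dcols = (go @ wm).reshape(n, h, width, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + h, j : j + width] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        x.grad += gxp[:, :, ph : ph + h, pw : pw + width]

    out._backward = _bw
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    n, c, width = x.data.shape
    w2 = width // size
    if w2 < 1:
        raise ValueError("pooling would empty the feature map")
    xc = x.data[:, :, : w2 * size].reshape(n, c, w2, size)
    idx = xc.argmax(axis=3)
    out = Tensor(np.take_along_axis(xc, idx[..., None], axis=3)[..., 0], (x,))

    def _bw():
        g = np.zeros_like(xc)
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=3)
        gx = np.zeros_like(x.data)
        gx[:, :, : w2 * size] = g.reshape(n, c, w2 * size)
        x.grad += gx

    out._backward = _bw
    return out


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    h2, w2 = h // size, w // size
    if h2 < 1 or w2 < 1:
        raise ValueError("pooling would empty the feature map")
    xc = (
        x.data[:, :, : h2 * size, : w2 * size]
        .reshape(n, c, h2, size, w2, size)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h2, w2, size * size)
    )
    idx = xc.argmax(axis=4)
    out = Tensor(np.take_along_axis(xc, idx[..., None], axis=4)[..., 0], (x,))

    def _bw():
        g = np.zeros_like(xc)
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=4)
        g = (
            g.reshape(n, c, h2, w2, size, size)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * size, w2 * size)
        )
        gx = np.zeros_like(x.data)
        gx[:, :, : h2 * size, : w2 * size] = g
        x.grad += gx

    out._backward = _bw
    return out
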