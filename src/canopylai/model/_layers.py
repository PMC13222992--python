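"""Parameterized layers and the Adam optimizer for the autograd engine."""

from __future__ import annotations

import numpy as np

from canopylai.model._autograd import Tensor, concat, conv1d, conv2d

__all__ = [
    "Module",
    "Dense",
    "Conv1D",
    "Conv2D",
    "GRULayer",
    "LayerNorm",
    "MultiHeadAttention",
    "Adam",
    "spatial_dropout",
]


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Anything with trainable tensors; submodules are discovered by attr."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, n_in, n_out))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1D(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * k, c_out * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = Tensor(rng.uniform(-limit, limit, size=(c_out, c_in, k)))
        self.b = Tensor(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Conv2D(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in, fan_out = c_in * k * k, c_out * k * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = Tensor(rng.uniform(-limit, limit, size=(c_out, c_in, k, k)))
        self.b = Tensor(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class GRULayer(Module):
    """A gated recurrent unit layer unrolled over a short sequence.

    Update gate z and reset gate r modulate how much of the previous
    hidden state survives each phenological timestep.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wz = Tensor(_glorot(rng, n_in, n_hidden))
        self.uz = Tensor(_glorot(rng, n_hidden, n_hidden))
        self.bz = Tensor(np.zeros(n_hidden))
        self.wr = Tensor(_glorot(rng, n_in, n_hidden))
        self.ur = Tensor(_glorot(rng, n_hidden, n_hidden))
        self.br = Tensor(np.zeros(n_hidden))
        self.wh = Tensor(_glorot(rng, n_in, n_hidden))
        self.uh = Tensor(_glorot(rng, n_hidden, n_hidden))
        self.bh = Tensor(np.zeros(n_hidden))

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        """Map a sequence of (N, F) tensors to the hidden-state sequence."""
        n = xs[0].shape[0]
        h = Tensor(np.zeros((n, self.n_hidden)))
        out = []
        for x in xs:
            z = (x @ self.wz + h @ self.uz + self.bz).sigmoid()
            r = (x @ self.wr + h @ self.ur + self.br).sigmoid()
            h_tilde = (x @ self.wh + (r * h) @ self.uh + self.bh).tanh()
            h = (1.0 - z) * h + z * h_tilde
            out.append(h)
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim))
        self.b = Tensor(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps) ** 0.5 * self.g + self.b


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("model width must be divisible by the head count")
        self.n_heads = n_heads
        self.dim = dim
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        hd = d // self.n_heads

        def split(v: Tensor) -> Tensor:  # (N,T,D) -> (N,heads,T,hd)
            return v.reshape(n, t, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(ctx)


def spatial_dropout(
    x: Tensor, rate: float, rng: np.random.Generator, training: bool
) -> Tensor:
    """Drop whole channels (axis 1), inverted scaling; identity at eval."""
    if not training or rate <= 0:
        return x
    shape = (x.shape[0], x.shape[1]) + (1,) * (x.ndim - 2)
    mask = (rng.random(shape) >= rate) / (1.0 - rate)
    return x * mask


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
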