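"""Neural building blocks on the autodiff core: linear/embedding layers,
layer norm, a 1-D convolution, an LSTM and a single-head causal attention
block.  Parameter init is explicit-rng so every model is a pure function of
its seed."""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .autograd import Tensor, cat, log_softmax, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Conv1d",
    "LSTM",
    "SelfAttention",
]


class Module:
    """Minimal parameter container with state-dict save/load."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: List[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.normal(0.0, 1.0, (n_in, n_out)) * scale, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.1, (n_vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W.take_rows(idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self._eps) ** 0.5) * self.gamma + self.beta


class Conv1d(Module):
    """1-D convolution over (batch, length, channels), valid padding.

    Implemented as a sum of shifted matmuls, which keeps the whole op inside
    the autodiff core.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        scale = 1.0 / np.sqrt(c_in * kernel)
        self.W = Tensor(rng.normal(0.0, 1.0, (kernel, c_in, c_out)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        L_out = L - self.kernel + 1
        if L_out < 1:
            raise ValueError(f"sequence length {L} shorter than kernel {self.kernel}")
        out = None
        for k in range(self.kernel):
            term = x[:, k : k + L_out, :] @ self.W[k]
            out = term if out is None else out + term
        return out + self.b


class LSTM(Module):
    """Single-layer LSTM over (batch, length, dim); returns all hidden states."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wx = Linear(n_in, 4 * n_hidden, rng)
        self.Wh = Linear(n_hidden, 4 * n_hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            gates = self.Wx(x[:, t, :]) + self.Wh(h)
            i = gates[:, :H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            o = gates[:, 2 * H : 3 * H].sigmoid()
            g = gates[:, 3 * H :].tanh()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, H))
        return cat(outs, axis=1)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention with optional masks."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
        """`mask` is an additive (B, L, L) or (L, L) array of 0 / -inf-like values."""
        q, k, v = self.Wq(x), self.Wk(x), self.Wv(x)
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(self.dim)
        if mask is not None:
            scores = scores + Tensor(mask)
        att = softmax(scores, axis=-1)
        return self.Wo(att @ v)
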