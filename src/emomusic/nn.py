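"""Neural building blocks for the EEG-to-audio sequence model.

Layers are thin parameter containers whose ``__call__`` builds an
autodiff graph (see :mod:`emomusic._autodiff`).  Initialisation is
always driven by an explicit :class:`numpy.random.Generator`, so a
model built twice from the same seed has identical weights.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import (Tensor, concat, embedding, gelu, layer_norm,
                        log_softmax, sigmoid, softmax, tanh)


class Module:
    """Base class: recursively collects parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, scale, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x) * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (n, d)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel heads.

    Attention weights of the most recent call are kept on
    ``last_attention`` (heads, L_q, L_k averaged over batch collapses are
    avoided: shape (..., heads, L_q, L_k)) for diagnostics.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        # near-identity Q/K init: queries and keys start aligned, so
        # attention is position-selective from the first step (the
        # sinusoidal PE rows are nearly orthogonal across positions) and
        # training budget goes into the content mapping instead of
        # rediscovering positional routing
        self.wq.weight.data += np.eye(d_model)
        self.wk.weight.data += np.eye(d_model)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        *b, L, _ = x.shape
        return x.reshape(*b, L, self.n_heads, self.d_head).swapaxes(-3, -2)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        *b, L, _ = q.shape
        qh, kh, vh = self._split(self.wq(q)), self._split(self.wk(k)), self._split(self.wv(v))
        scores = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = (attn @ vh).swapaxes(-3, -2).reshape(*b, L, self.d_model)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class EncoderLayer(Module):
    """Pre-norm transformer encoder block (self-attention + FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, h)
        return x + self.ff(self.ln2(x))


class DecoderLayer(Module):
    """Pre-norm decoder block: self-attention, cross-attention, FFN.

    Self-attention is bidirectional — the decoder infills masked
    positions rather than generating left-to-right.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ln3 = LayerNorm(d_model)

    def __call__(self, x: Tensor, memory: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.self_attn(h, h, h)
        x = x + self.cross_attn(self.ln2(x), memory, memory)
        return x + self.ff(self.ln3(x))


class LSTMLayer(Module):
    """Single-direction LSTM, unrolled over the sequence axis.

    Ablation backbone only; the reference architecture is the
    transformer encoder/decoder above.
    """

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.d_model = d_model
        self.wx = Linear(d_model, 4 * d_model, rng)
        self.wh = Linear(d_model, 4 * d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        *b, L, d = x.shape
        flat = x.reshape(-1, L, d)
        B = flat.shape[0]
        h = Tensor(np.zeros((B, 1, d)))
        c = Tensor(np.zeros((B, 1, d)))
        outs = []
        for t in range(L):
            xt = _take_step(flat, t)               # (B, 1, d)
            z = self.wx(xt) + self.wh(h)
            zi, zf, zo, zg = _split4(z, d)
            i, f, o, g = sigmoid(zi), sigmoid(zf), sigmoid(zo), tanh(zg)
            c = f * c + i * g
            h = o * tanh(c)
            outs.append(h)
        out = concat(outs, axis=1)                  # (B, L, d)
        return out.reshape(*b, L, d)


def _take_step(x: Tensor, t: int) -> Tensor:
    """x[:, t:t+1, :] for a 3-D tensor, with gradient."""
    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, t:t + 1, :] = g
        return (gx,)
    return x._make(x.data[:, t:t + 1, :], (x,), backward)


def _split4(z: Tensor, d: int):
    def piece(k):
        def backward(g):
            gz = np.zeros_like(z.data)
            gz[..., k * d:(k + 1) * d] = g
            return (gz,)
        return z._make(z.data[..., k * d:(k + 1) * d], (z,), backward)
    return piece(0), piece(1), piece(2), piece(3)


class Adam:
    """Standard Adam optimiser."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = ["Module", "Linear", "LayerNorm", "Embedding", "MultiHeadAttention",
           "FeedForward", "EncoderLayer", "DecoderLayer", "LSTMLayer", "Adam",
           "log_softmax", "softmax"]
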