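"""Model-ready token sequences.

A token at sequence position ``pos`` is the element-wise sum of three
``d_model`` vectors:

* **content** — the output of a convolutional frontend applied to the
  raw window (EEG: channels x samples; audio: waveform),
* **ID embedding** — a learned table row for the frame's dictionary ID
  (the discrete vocabulary entry, including ``unk``), and
* **positional encoding** — fixed sinusoids,
  ``PE(pos, 2i) = sin(pos / 10000^(2i/d_model))``,
  ``PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model))``.

The conv frontend here is a fixed random-weight featurizer: its weights
are drawn once from a seeded generator and never trained.  Fixed random
convolutional projections are a standard cheap featurizer; the learnable
mapping is carried by the dictionary-ID embeddings and the transformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stream
from .discretize import DiscreteSequence


class InvalidModelConfigError(ValueError):
    pass


@dataclass
class PositionalEncoding:
    matrix: np.ndarray          # L x d_model
    d_model: int


@dataclass
class ContentFeatures:
    matrix: np.ndarray          # L x d_model
    modality: str


@dataclass
class TokenSequence:
    """Content features + discrete IDs for one trial's windows.

    The learned ID embedding is added inside the model (it is a trained
    parameter), so a TokenSequence carries the content matrix and the
    IDs separately; the full token matrix is formed at model input time
    as content + embed(ids) + PE.
    """

    content: np.ndarray         # L x d_model
    ids: DiscreteSequence
    modality: str
    subject_id: int = 0
    trial_id: int = 0

    def __post_init__(self):
        if self.content.shape[0] != len(self.ids):
            raise ValueError("content length != id sequence length")

    def __len__(self):
        return self.content.shape[0]

    @property
    def d_model(self) -> int:
        return self.content.shape[1]


def positional_encoding(L: int, d_model: int) -> PositionalEncoding:
    """Sinusoidal encoding; wavelengths span 2*pi to 10000*2*pi."""
    if d_model % 2:
        raise InvalidModelConfigError("d_model must be even (sin/cos pairs)")
    if L < 1:
        raise InvalidModelConfigError("L must be >= 1")
    pos = np.arange(L, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((L, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return PositionalEncoding(pe, d_model)


class ConvFrontend:
    """Fixed random 3-layer 1-D conv stack producing one vector per window.

    Kernels 7-5-3 with decimating strides, GELU between layers, a mean
    pool over the remaining time axis, layer normalisation and a final
    linear projection to ``d_model``.  Weights come from a seeded
    generator; ``bias=False`` keeps the stack linear through zero.
    """

    def __init__(self, in_channels: int, d_model: int, seed: int,
                 modality: str, hidden: tuple[int, ...] = (32, 64, 64),
                 kernels: tuple[int, ...] = (7, 5, 3),
                 strides: tuple[int, ...] = (4, 4, 4), bias: bool = False):
        rng = stream(seed, "frontend", modality)
        self.modality = modality
        self.d_model = d_model
        self.kernels, self.strides = kernels, strides
        self.weights, self.biases = [], []
        c_in = in_channels
        for c_out, k in zip(hidden, kernels):
            scale = np.sqrt(2.0 / (c_in * k))
            self.weights.append(rng.normal(0.0, scale, (c_out, c_in, k)))
            self.biases.append(rng.normal(0.0, 0.1, c_out) if bias
                               else np.zeros(c_out))
            c_in = c_out
        self.proj = rng.normal(0.0, np.sqrt(1.0 / c_in), (c_in, d_model))

    @staticmethod
    def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                stride: int) -> np.ndarray:
        c_out, c_in, k = w.shape
        n = x.shape[1]
        if n < k:
            raise ValueError(f"window of {n} samples shorter than kernel {k}")
        starts = np.arange(0, n - k + 1, stride)
        patches = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)[:, starts]
        out = np.einsum("cpk,ock->op", patches, w) + b[:, None]
        return out

    @staticmethod
    def _gelu(x):
        return 0.5 * x * (1.0 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x ** 3)))

    def _one(self, window: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(window, dtype=np.float64))
        if x.shape[0] != self.weights[0].shape[1]:
            raise ValueError(
                f"expected {self.weights[0].shape[1]} input channels, "
                f"got {x.shape[0]}")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = self._conv1d(x, w, b, self.strides[i])
            if i < len(self.weights) - 1:
                x = self._gelu(x)
        v = x.mean(axis=1)
        norm = np.linalg.norm(v)
        if norm > 0:
            mu, sd = v.mean(), v.std()
            v = (v - mu) / (sd if sd > 0 else 1.0)
        return v @ self.proj

    def __call__(self, windows) -> ContentFeatures:
        return ContentFeatures(np.stack([self._one(w) for w in windows]),
                               self.modality)


def cnn_content_features(windows, modality: str, d_model: int,
                         seed: int) -> ContentFeatures:
    """Content features for a list of raw windows via a seeded frontend."""
    first = np.atleast_2d(np.asarray(windows[0]))
    frontend = ConvFrontend(first.shape[0], d_model, seed, modality)
    return frontend([np.atleast_2d(np.asarray(w)) for w in windows])


def assemble_tokens(content: ContentFeatures, ids: DiscreteSequence,
                    pe: PositionalEncoding,
                    embedding_table: np.ndarray) -> np.ndarray:
    """Sum content + embed(ids) + PE into an L x d_model token matrix.

    ``embedding_table`` must have ``vocab_size`` rows (dictionary entries
    plus unk).  Used for fixed-weight inspection; the trained model
    performs the same composition with its learned table inside the
    autodiff graph.
    """
    L, d = content.matrix.shape
    if len(ids) != L:
        raise ValueError("length mismatch between content and ids")
    if pe.matrix.shape[0] < L or pe.d_model != d:
        raise ValueError("positional encoding does not cover the sequence")
    if ids.ids.max() >= embedding_table.shape[0] or ids.ids.min() < 0:
        raise ValueError("dictionary ID outside embedding-table range")
    return content.matrix + embedding_table[ids.ids] + pe.matrix[:L]
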