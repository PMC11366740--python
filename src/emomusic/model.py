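"""EEG-to-audio-token sequence model with masked-prediction training.

The network is a transformer encoder–decoder.  The encoder reads EEG
tokens (content + dictionary-ID embedding + positional encoding) through
``d_layers`` self-attention blocks.  The decoder reads audio tokens in
which a random subset of positions has been replaced by a learned mask
embedding (plus positional encoding), attends to the encoder output
through cross-attention, and predicts the audio dictionary ID at every
position.  Decoder self-attention is bidirectional — this is an
infilling objective, not autoregressive generation.

Training minimises the composite loss

    FL = (1 - alpha) * FLm + alpha * FLu

where ``FLm`` is the mean negative log-likelihood of the true IDs at
masked positions and ``FLu`` the same quantity at unmasked positions.
``alpha`` < 0.5 keeps the objective mask-dominant, which forces the
model to reconstruct hidden audio structure from context and the EEG
conditioning.

The public surface follows the model/results convention:
:class:`EEGMusicModel` is built from paired token sequences, and
:meth:`EEGMusicModel.fit` returns an :class:`EEGMusicResults` carrying
the trained parameters, the loss history and evaluation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from ._autodiff import Tensor, embedding, gather_rows, log_softmax
from ._rng import derive_seed, stream
from .discretize import DiscreteSequence
from .tokens import PositionalEncoding, TokenSequence, positional_encoding


class UndefinedLossError(ValueError):
    """Loss requested over an empty position set."""


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``d_layers`` defaults to the depth at which the reference
    architecture peaks (12); small-scale experiments typically override
    it to 2.
    """

    d_layers: int = 12
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 256
    dropout: float = 0.0
    alpha: float = 0.2
    mask_ratio: float = 0.5
    seed: int = 0
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 10
    backbone: str = "transformer"
    aligned_memory: bool = True

    def __post_init__(self):
        if self.d_layers < 1:
            raise ModelConfigError("d_layers must be >= 1")
        if self.d_model % 2:
            raise ModelConfigError("d_model must be even")
        if self.d_model % self.n_heads:
            raise ModelConfigError("d_model must be divisible by n_heads")
        for name in ("alpha", "mask_ratio", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelConfigError(f"{name} must be in [0, 1]")
        if self.backbone not in ("transformer", "lstm", "cnn"):
            raise ModelConfigError(f"unknown backbone {self.backbone!r}")


@dataclass
class MaskedBatch:
    """Audio token sequence with a masked-position index set T."""

    tokens: np.ndarray            # L x d_model, masked rows replaced
    mask_set: np.ndarray          # sorted indices in T
    reference_ids: np.ndarray     # true dictionary IDs, all positions
    content: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.reference_ids.size

    @property
    def unmasked_set(self) -> np.ndarray:
        m = np.ones(self.L, dtype=bool)
        m[self.mask_set] = False
        return np.flatnonzero(m)


@dataclass
class DecoderOutput:
    hidden: np.ndarray            # L x d_model
    logits: np.ndarray            # L x V
    probs: np.ndarray             # row-stochastic
    predicted_ids: np.ndarray


@dataclass
class LossValue:
    total: float
    masked: float
    unmasked: float
    alpha: float


def choose_mask(L: int, mask_ratio: float, seed: int) -> np.ndarray:
    """Sorted set of round(mask_ratio * L) positions, without replacement."""
    if not 0.0 <= mask_ratio <= 1.0:
        raise ModelConfigError("mask_ratio must be in [0, 1]")
    n_mask = int(round(mask_ratio * L))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(L, size=n_mask, replace=False))


def apply_mask(audio_tokens: TokenSequence, mask_ratio: float, seed: int,
               mask_vector: np.ndarray | None = None,
               embedding_table: np.ndarray | None = None) -> MaskedBatch:
    """Mask a token sequence: masked rows become mask_vector + PE.

    With no ``mask_vector`` given, a zero vector stands in (the trained
    model substitutes its learned mask embedding when it builds the
    decoder input inside the autodiff graph).
    """
    L, d = audio_tokens.content.shape
    mask_set = choose_mask(L, mask_ratio, seed)
    pe = positional_encoding(max(L, 1), d).matrix
    emb = (embedding_table[audio_tokens.ids.ids]
           if embedding_table is not None else 0.0)
    tokens = audio_tokens.content + emb + pe
    mv = np.zeros(d) if mask_vector is None else mask_vector
    tokens[mask_set] = mv + pe[mask_set]
    return MaskedBatch(tokens, mask_set, audio_tokens.ids.ids.copy(),
                       content=audio_tokens.content)


def composite_loss(flm: float, flu: float, alpha: float) -> LossValue:
    """FL = (1 - alpha) * FLm + alpha * FLu."""
    if not 0.0 <= alpha <= 1.0:
        raise ModelConfigError("alpha must be in [0, 1]")
    return LossValue((1.0 - alpha) * flm + alpha * flu, flm, flu, alpha)


def nll_at_positions(probs: np.ndarray, reference_ids: np.ndarray,
                     positions: np.ndarray) -> float:
    """Mean -log p(reference) over the given positions (closed form)."""
    positions = np.asarray(positions, dtype=np.intp)
    if positions.size == 0:
        raise UndefinedLossError("no positions to evaluate the loss on")
    p = probs[positions, reference_ids[positions]]
    return float(-np.log(np.maximum(p, 1e-300)).mean())


def masked_loss(out: DecoderOutput, masked: MaskedBatch) -> float:
    """FLm: mean NLL of the reference IDs at masked positions."""
    return nll_at_positions(out.probs, masked.reference_ids, masked.mask_set)


def unmasked_loss(out: DecoderOutput, masked: MaskedBatch) -> float:
    """FLu: the same NLL over the complement of the mask set."""
    return nll_at_positions(out.probs, masked.reference_ids,
                            masked.unmasked_set)


class _Network(nn.Module):
    """Parameter container + graph builder for one backbone."""

    def __init__(self, cfg: ModelConfig, eeg_vocab: int, audio_vocab: int):
        rng = stream(cfg.seed, "init")
        d = cfg.d_model
        self.cfg = cfg
        self.eeg_vocab, self.audio_vocab = eeg_vocab, audio_vocab
        self.eeg_embed = nn.Embedding(eeg_vocab, d, rng)
        self.audio_embed = nn.Embedding(audio_vocab, d, rng)
        # embeddings are scaled by sqrt(d_model) at composition (the
        # standard recipe), so their magnitude matches the unit-amplitude
        # sinusoidal positional encoding instead of being drowned by it
        self.embed_scale = float(np.sqrt(d))
        self.mask_embed = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (d,)),
                                 requires_grad=True)
        if cfg.backbone == "transformer":
            self.enc_layers = [nn.EncoderLayer(d, cfg.n_heads, cfg.d_ff, rng)
                               for _ in range(cfg.d_layers)]
            self.dec_layers = [nn.DecoderLayer(d, cfg.n_heads, cfg.d_ff, rng)
                               for _ in range(cfg.d_layers)]
        elif cfg.backbone == "lstm":
            self.enc_layers = [nn.LSTMLayer(d, rng) for _ in range(cfg.d_layers)]
            self.dec_layers = [nn.LSTMLayer(d, rng) for _ in range(cfg.d_layers)]
        else:                                   # "cnn": token-wise MLP stub
            self.enc_layers = [nn.FeedForward(d, cfg.d_ff, rng)
                               for _ in range(cfg.d_layers)]
            self.dec_layers = [nn.FeedForward(d, cfg.d_ff, rng)
                               for _ in range(cfg.d_layers)]
        self.enc_norm = nn.LayerNorm(d)
        self.dec_norm = nn.LayerNorm(d)
        self.head = nn.Linear(d, audio_vocab, rng)

    # tokens: content (B,L,d) const; ids (B,L) ints
    def _compose(self, content: np.ndarray, ids: np.ndarray,
                 embed: nn.Embedding, pe: np.ndarray) -> Tensor:
        return embed(ids) * self.embed_scale + Tensor(content + pe[: content.shape[-2]])

    def encode(self, content: np.ndarray, ids: np.ndarray) -> Tensor:
        L = content.shape[-2]
        pe = positional_encoding(L, self.cfg.d_model).matrix
        x = self._compose(content, ids, self.eeg_embed, pe)
        for layer in self.enc_layers:
            x = layer(x)
        return self.enc_norm(x)

    def decode(self, content: np.ndarray, ids: np.ndarray,
               mask: np.ndarray, memory: Tensor) -> Tensor:
        """Decoder logits; ``mask`` is a boolean (B, L) array."""
        if content.shape[-2] == 0:
            raise ValueError("decoder input of length 0")
        B_L = content.shape[:-1]
        L, d = content.shape[-2], content.shape[-1]
        pe = positional_encoding(L, d).matrix
        m = mask.astype(np.float64)[..., None]
        visible = self.audio_embed(ids) * self.embed_scale + Tensor(content)
        x = visible * Tensor(1.0 - m) + (self.mask_embed * self.embed_scale) * Tensor(m) + Tensor(
            np.broadcast_to(pe, content.shape).copy())
        if self.cfg.aligned_memory and memory.shape[-2] == L:
            # EEG and audio windows share one clock, so the encoder state
            # of the same frame is injected additively; cross-attention
            # still lets the decoder consult the rest of the sequence
            x = x + memory
        for layer in self.dec_layers:
            if self.cfg.backbone == "transformer":
                x = layer(x, memory)
            elif self.cfg.backbone == "lstm":
                x = layer(x + memory.mean(axis=-2, keepdims=True))
            else:
                x = x + layer(x + memory.mean(axis=-2, keepdims=True))
        return self.head(self.dec_norm(x))


def encode(eeg_tokens: TokenSequence, cfg: ModelConfig,
           eeg_vocab: int | None = None) -> np.ndarray:
    """Standalone encoder pass (seeded random initialisation)."""
    if eeg_tokens.d_model != cfg.d_model:
        raise ModelConfigError(
            f"token d_model {eeg_tokens.d_model} != config {cfg.d_model}")
    vocab = eeg_vocab or int(eeg_tokens.ids.ids.max()) + 1
    net = _Network(cfg, vocab, max(vocab, 2))
    out = net.encode(eeg_tokens.content, eeg_tokens.ids.ids)
    return out.data


class EEGMusicModel:
    """EEG-to-audio-token model over paired token sequences.

    Parameters
    ----------
    pairs
        list of ``(eeg: TokenSequence, audio: TokenSequence)`` tuples,
        all of the same length L (one pair per trial).
    eeg_vocab, audio_vocab
        vocabulary sizes including the unk token.
    config
        :class:`ModelConfig`.
    """

    def __init__(self, pairs, eeg_vocab: int, audio_vocab: int,
                 config: ModelConfig | None = None):
        if len(pairs) < 1:
            raise ValueError("need at least one training pair")
        self.pairs = list(pairs)
        self.eeg_vocab = int(eeg_vocab)
        self.audio_vocab = int(audio_vocab)
        self.config = config or ModelConfig()
        lengths = {len(e) for e, a in self.pairs} | {len(a) for e, a in self.pairs}
        if len(lengths) != 1:
            raise ValueError("all token sequences must share one length")
        self.L = lengths.pop()
        self._eeg_content = np.stack([e.content for e, _ in self.pairs])
        self._eeg_ids = np.stack([e.ids.ids for e, _ in self.pairs])
        self._audio_content = np.stack([a.content for _, a in self.pairs])
        self._audio_ids = np.stack([a.ids.ids for _, a in self.pairs])

    def fit(self, epochs: int | None = None, verbose: bool = False
            ) -> "EEGMusicResults":
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        net = _Network(cfg, self.eeg_vocab, self.audio_vocab)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        history = []
        n = len(self.pairs)
        order_rng = stream(cfg.seed, "batch-order")
        for epoch in range(epochs):
            order = order_rng.permutation(n)
            ep_flm, ep_flu, ep_w = [], [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                mask = np.zeros((idx.size, self.L), dtype=bool)
                for j, b in enumerate(idx):
                    mask[j, choose_mask(self.L, cfg.mask_ratio,
                                        derive_seed(cfg.seed, "mask", epoch, b))] = True
                loss, flm, flu = self._step_loss(net, idx, mask)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(FLm={flm}, FLu={flu}); aborting")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_flm.append(flm)
                ep_flu.append(flu)
                ep_w.append(idx.size)
            w = np.asarray(ep_w, dtype=float)
            flm = float(np.average(ep_flm, weights=w))
            flu = float(np.average(ep_flu, weights=w))
            fl = composite_loss(flm, flu, cfg.alpha).total
            history.append({"epoch": epoch, "FLm": flm, "FLu": flu, "FL": fl})
            if verbose:
                print(f"epoch {epoch:3d}  FL {fl:.4f}  FLm {flm:.4f}  FLu {flu:.4f}")
        return EEGMusicResults(self, net, pd.DataFrame(history))

    def _step_loss(self, net: _Network, idx: np.ndarray, mask: np.ndarray):
        memory = net.encode(self._eeg_content[idx], self._eeg_ids[idx])
        logits = net.decode(self._audio_content[idx], self._audio_ids[idx],
                            mask, memory)
        logp = log_softmax(logits, axis=-1)
        B, L, V = logp.shape
        flat = logp.reshape(B * L, V)
        refs = self._audio_ids[idx].reshape(-1)
        mflat = mask.reshape(-1)
        m_idx = np.flatnonzero(mflat)
        u_idx = np.flatnonzero(~mflat)
        if m_idx.size == 0:
            raise UndefinedLossError("empty mask set in training batch")
        flm_t = -(gather_rows(flat, m_idx, refs[m_idx]).mean())
        flu_t = -(gather_rows(flat, u_idx, refs[u_idx]).mean()) if u_idx.size \
            else Tensor(0.0)
        loss = flm_t * (1.0 - net.cfg.alpha) + flu_t * net.cfg.alpha
        return loss, float(flm_t.data), float(flu_t.data)


class EEGMusicResults:
    """Fitted model: parameters, loss history, prediction and summary."""

    def __init__(self, model: EEGMusicModel, network: _Network,
                 loss_history: pd.DataFrame):
        self.model = model
        self.network = network
        self.loss_history = loss_history
        self.config = model.config

    # -- prediction ----------------------------------------------------
    def predict_proba(self, eeg: TokenSequence, audio: TokenSequence,
                      mask_set: np.ndarray) -> DecoderOutput:
        """Decoder distribution with the given audio positions masked."""
        L = len(audio)
        mask = np.zeros((1, L), dtype=bool)
        mask[0, np.asarray(mask_set, dtype=np.intp)] = True
        memory = self.network.encode(eeg.content[None], eeg.ids.ids[None])
        logits = self.network.decode(audio.content[None], audio.ids.ids[None],
                                     mask, memory)
        lse = log_softmax(logits, axis=-1).data[0]
        probs = np.exp(lse)
        return DecoderOutput(hidden=logits.data[0], logits=logits.data[0],
                             probs=probs, predicted_ids=probs.argmax(axis=1))

    def generate(self, eeg: TokenSequence, L_audio: int | None = None
                 ) -> DiscreteSequence:
        """Predict audio IDs with every position masked (pure generation)."""
        L = L_audio or len(eeg)
        d = self.config.d_model
        dummy = TokenSequence(np.zeros((L, d)),
                              DiscreteSequence(np.zeros(L, dtype=np.int64),
                                               np.arange(L)), "audio")
        out = self.predict_proba(eeg, dummy, np.arange(L))
        return DiscreteSequence(out.predicted_ids, np.arange(L))

    # -- evaluation ----------------------------------------------------
    def evaluate_pairs(self, pairs, mask_seed: int = 0,
                       k_values=(1, 3, 5, 10, 20), framing: str = "masked",
                       n_draws: int = 1):
        """Hits@k over held-out pairs.

        ``framing="masked"`` scores the positions hidden at
        ``config.mask_ratio``; ``framing="generation"`` masks and scores
        every position.  ``n_draws`` > 1 pools several independent mask
        draws per pair (masked framing only), which grows the evaluated
        position count and steadies the estimate on short sequences.
        """
        from .evaluate import hits_at_k
        all_probs, all_refs, all_pos, offset = [], [], [], 0
        draws = 1 if framing == "generation" else max(1, int(n_draws))
        for j, (eeg, audio) in enumerate(pairs):
            L = len(audio)
            for r in range(draws):
                if framing == "generation":
                    mask_set = np.arange(L)
                else:
                    mask_set = choose_mask(L, self.config.mask_ratio,
                                           derive_seed(mask_seed, "eval", j, r))
                out = self.predict_proba(eeg, audio, mask_set)
                all_probs.append(out.probs)
                all_refs.append(audio.ids.ids)
                all_pos.append(mask_set + offset)
                offset += L
        probs = np.concatenate(all_probs)
        refs = np.concatenate(all_refs)
        pos = np.concatenate(all_pos)
        return hits_at_k(probs, refs, pos, k_values=list(k_values))

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        last = self.loss_history.iloc[-1] if len(self.loss_history) else None
        lines = [
            "EEG-to-music token model",
            "=" * 40,
            f"backbone:        {cfg.backbone}",
            f"layers (d):      {cfg.d_layers}",
            f"d_model / heads: {cfg.d_model} / {cfg.n_heads}",
            f"EEG vocab:       {self.model.eeg_vocab}",
            f"audio vocab:     {self.model.audio_vocab}",
            f"alpha / mask:    {cfg.alpha} / {cfg.mask_ratio}",
            f"parameters:      {self.network.n_parameters()}",
            f"training pairs:  {len(self.model.pairs)} x L={self.model.L}",
        ]
        if last is not None:
            lines.append(f"final loss FL:   {last['FL']:.4f} "
                         f"(FLm {last['FLm']:.4f}, FLu {last['FLu']:.4f})")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for col in ("FL", "FLm", "FLu"):
            ax.plot(self.loss_history["epoch"], self.loss_history[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss (nats)")
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------
    def save(self, path):
        import json
        from pathlib import Path
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 *[p.data for p in self.network.parameters()])
        meta = {"config": self.config.__dict__,
                "eeg_vocab": self.model.eeg_vocab,
                "audio_vocab": self.model.audio_vocab,
                "loss_history": self.loss_history.to_dict(orient="list")}
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path.with_suffix(".npz")
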