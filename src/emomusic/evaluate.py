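"""Evaluation: Hits@k ranking, subject-wise splits, the ablation
harness, and waveform reconstruction from predicted audio tokens.

Hits@k is the fraction of evaluated positions whose reference dictionary
ID ranks within the top-k model scores,

    Hits@k = (1/n) * sum_i 1[rank_i <= k],

with rank 1 the best.  Ties resolve toward the lower index, which is
deterministic and never flatters the reference.  Chance level for a
uniform scorer is k / V for vocabulary size V.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import idct, irfft, rfft

from ._rng import derive_seed, stream
from .discretize import (DiscreteSequence, FeatureDictionary, fit_dictionary,
                         encode_sequence)
from .features import mel_filterbank
from .preproc import AudioTrack

DEFAULT_K_VALUES = (1, 3, 5, 10, 20)


class UndefinedMetricError(ValueError):
    pass


class InvalidSplitError(ValueError):
    pass


class ModalityError(ValueError):
    pass


@dataclass
class HitsResult:
    k_values: tuple[int, ...]
    hits: dict[int, float]
    n: int
    ranks: np.ndarray

    def as_percent(self) -> dict[int, float]:
        return {k: 100.0 * v for k, v in self.hits.items()}


@dataclass
class SplitSpec:
    train_subjects: tuple[int, ...]
    test_subjects: tuple[int, ...]
    ratio: float
    seed: int


@dataclass(frozen=True)
class AblationSpec:
    """Which pipeline pieces to keep for a Table-3-style arm."""

    use_eeg_clustering: bool = True
    use_audio_clustering: bool = True
    backbone: str = "transformer"
    d_layers: int = 2

    def __post_init__(self):
        if self.backbone not in ("transformer", "lstm", "cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def hits_at_k(probs: np.ndarray, reference_ids: np.ndarray,
              positions: np.ndarray | None = None,
              k_values=list(DEFAULT_K_VALUES)) -> HitsResult:
    """Hits@k of reference IDs under row-stochastic scores.

    ``rank_i = 1 + #{j : p_j > p_ref} + #{j < ref : p_j == p_ref}``.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    reference_ids = np.asarray(reference_ids, dtype=np.intp)
    if positions is None:
        positions = np.arange(probs.shape[0])
    positions = np.asarray(positions, dtype=np.intp)
    if positions.size == 0:
        raise UndefinedMetricError("no positions to evaluate")
    if reference_ids.max() >= probs.shape[1] or reference_ids.min() < 0:
        raise UndefinedMetricError("reference ID outside vocabulary")
    ranks = np.empty(positions.size, dtype=np.int64)
    for out_i, i in enumerate(positions):
        ref = reference_ids[i]
        row = probs[i]
        higher = int(np.sum(row > row[ref]))
        tied_before = int(np.sum(row[:ref] == row[ref]))
        ranks[out_i] = 1 + higher + tied_before
    hits = {int(k): float(np.mean(ranks <= k)) for k in k_values}
    return HitsResult(tuple(int(k) for k in k_values), hits,
                      int(positions.size), ranks)


def split_subjects(subject_ids, ratio: float = 0.2,
                   seed: int = 0) -> SplitSpec:
    """Seeded shuffle-then-split of subjects; test share = round(ratio*n)."""
    subject_ids = list(subject_ids)
    if len(subject_ids) < 5:
        raise InvalidSplitError(
            f"{len(subject_ids)} subjects cannot support a {ratio:.0%} test split")
    rng = np.random.default_rng(derive_seed(seed, "split"))
    order = rng.permutation(len(subject_ids))
    n_test = int(round(ratio * len(subject_ids)))
    n_test = max(1, n_test)
    test = tuple(sorted(subject_ids[i] for i in order[:n_test]))
    train = tuple(sorted(subject_ids[i] for i in order[n_test:]))
    return SplitSpec(train, test, ratio, seed)


# ---------------------------------------------------------------------------
# clustering-off ablation arm: quantile binning


class QuantileBinEncoder:
    """Discrete IDs without clustering, for the ablation arms.

    Each feature dimension is cut at its within-training-set median
    (2 uniform-probability bins); a frame's bin tuple is looked up in a
    frequency-ranked vocabulary of observed tuples, capped at
    ``max_vocab`` entries, with unseen/rare tuples mapping to unk.
    """

    def __init__(self, frames: np.ndarray, max_vocab: int = 64):
        frames = np.atleast_2d(frames)
        self.thresholds = np.median(frames, axis=0)
        codes = [tuple(row) for row in (frames > self.thresholds).astype(int)]
        from collections import Counter
        counts = Counter(codes)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self.vocab = {code: i for i, (code, _) in enumerate(ranked[:max_vocab])}
        self.unk_id = len(self.vocab)

    @property
    def vocab_size(self) -> int:
        return self.unk_id + 1

    def encode(self, frames: np.ndarray) -> DiscreteSequence:
        frames = np.atleast_2d(frames)
        ids = np.array([self.vocab.get(tuple(row), self.unk_id)
                        for row in (frames > self.thresholds).astype(int)])
        return DiscreteSequence(ids, np.arange(frames.shape[0]))


# ---------------------------------------------------------------------------
# experiment harness


def run_experiment(dataset, ablation: AblationSpec, model_cfg,
                   split_seed: int = 0, out_dir: str | Path | None = None,
                   k_values=DEFAULT_K_VALUES, low_hz: float = 4.0,
                   high_hz: float = 45.0, window_s: float = 4.0,
                   dbscan_params=None, n_eval_draws: int = 1) -> dict:
    """Train on 80% of subjects, evaluate Hits@k on the held-out 20%.

    ``dataset`` is the synthdata trial list (dicts with eeg/audio/latent).
    Dictionaries (or quantile-bin encoders for clustering-off arms) are
    fitted on training subjects only.  The report carries both the
    masked-position and the all-masked ("generation") framings.
    """
    from . import features as ft
    from . import preproc as pp
    from .model import EEGMusicModel, ModelConfig
    from .tokens import ConvFrontend, TokenSequence

    if not dataset:
        raise InvalidSplitError("empty dataset")
    cfg = model_cfg
    subjects = sorted({t["subject_id"] for t in dataset})
    split = split_subjects(subjects, seed=split_seed)

    segs, eeg_feats, audio_feats = [], [], []
    for t in dataset:
        eeg = pp.bandpass_filter(t["eeg"], low_hz, high_hz)
        eeg = pp.remove_baseline(eeg)
        audio = pp.normalize_audio(t["audio"])
        seg = pp.segment_windows(eeg, audio, window_s)
        segs.append((t, seg))
        eeg_feats.append(ft.window_de_features(seg))
        audio_feats.append(ft.window_audio_features(seg))

    train_rows = [i for i, (t, _) in enumerate(segs)
                  if t["subject_id"] in split.train_subjects]
    test_rows = [i for i, (t, _) in enumerate(segs)
                 if t["subject_id"] in split.test_subjects]
    eeg_train = np.concatenate([eeg_feats[i] for i in train_rows])
    aud_train = np.concatenate([audio_feats[i] for i in train_rows])

    eeg_params = audio_params = None
    if dbscan_params is not None:
        eeg_params, audio_params = dbscan_params
    audio_dict = None
    if ablation.use_eeg_clustering:
        eeg_dict = fit_dictionary(eeg_train, "eeg", params=eeg_params)
        enc_eeg = lambda x: encode_sequence(x, eeg_dict)
        eeg_vocab = eeg_dict.vocab_size
    else:
        qb = QuantileBinEncoder(eeg_train)
        enc_eeg, eeg_vocab = qb.encode, qb.vocab_size
    if ablation.use_audio_clustering:
        audio_dict = fit_dictionary(aud_train, "audio", params=audio_params)
        enc_aud = lambda x: encode_sequence(x, audio_dict)
        audio_vocab = audio_dict.vocab_size
    else:
        qa = QuantileBinEncoder(aud_train)
        enc_aud, audio_vocab = qa.encode, qa.vocab_size

    eeg_frontend = ConvFrontend(segs[0][1].eeg_windows[0].shape[0],
                                cfg.d_model, cfg.seed, "eeg")
    audio_frontend = ConvFrontend(1, cfg.d_model, cfg.seed, "audio",
                                  strides=(8, 8, 4))

    def tokens_for(i):
        t, seg = segs[i]
        e_content = eeg_frontend(seg.eeg_windows).matrix
        a_content = audio_frontend([w[None, :] for w in seg.audio_windows]).matrix
        e_ids = enc_eeg(eeg_feats[i])
        a_ids = enc_aud(audio_feats[i])
        return (TokenSequence(e_content, e_ids, "eeg", t["subject_id"], t["trial_id"]),
                TokenSequence(a_content, a_ids, "audio", t["subject_id"], t["trial_id"]))

    train_pairs = [tokens_for(i) for i in train_rows]
    test_pairs = [tokens_for(i) for i in test_rows]

    cfg = ModelConfig(**{**cfg.__dict__, "d_layers": ablation.d_layers,
                         "backbone": ablation.backbone})
    res = EEGMusicModel(train_pairs, eeg_vocab, audio_vocab, cfg).fit()
    hits_masked = res.evaluate_pairs(test_pairs, mask_seed=cfg.seed,
                                     k_values=k_values, framing="masked",
                                     n_draws=n_eval_draws)
    hits_gen = res.evaluate_pairs(test_pairs, mask_seed=cfg.seed,
                                  k_values=k_values, framing="generation")

    report = {
        "ablation": ablation.__dict__,
        "config": cfg.__dict__,
        "split": {"train": list(split.train_subjects),
                  "test": list(split.test_subjects), "seed": split_seed},
        "vocab": {"eeg": eeg_vocab, "audio": audio_vocab},
        "hits_masked": {str(k): v for k, v in hits_masked.hits.items()},
        "hits_generation": {str(k): v for k, v in hits_gen.hits.items()},
        "n_masked": hits_masked.n,
        "n_generation": hits_gen.n,
        "final_loss": res.loss_history.iloc[-1].to_dict(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = (f"{ablation.backbone}_d{ablation.d_layers}"
               f"_eeg{int(ablation.use_eeg_clustering)}"
               f"_aud{int(ablation.use_audio_clustering)}")
        (out_dir / f"report_{tag}.json").write_text(json.dumps(report, indent=1))
        import csv
        csv_path = out_dir / "reports.csv"
        row = {"tag": tag, **{f"hits@{k}": report["hits_masked"][str(k)]
                              for k in k_values}}
        write_header = not csv_path.exists()
        with csv_path.open("a", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(row))
            if write_header:
                w.writeheader()
            w.writerow(row)
    report["_results"] = res
    report["_test_pairs"] = test_pairs
    report["_train_pairs"] = train_pairs
    report["_audio_dict"] = audio_dict
    return report


# ---------------------------------------------------------------------------
# waveform reconstruction


def reconstruct_audio(ids: DiscreteSequence, dictionary: FeatureDictionary,
                      rate_hz: float, window_s: float = 4.0,
                      n_mels: int = 40, n_coef: int = 20,
                      n_iter: int = 32, seed: int = 0) -> AudioTrack:
    """Waveform from predicted audio-token IDs.

    Each ID's MFCC centroid is inverted to a mel spectral envelope
    (inverse DCT, exponential), the envelope lifted to a linear power
    spectrum through the filterbank pseudo-inverse, held constant over
    the token's window, and a waveform recovered by iterative phase
    reconstruction (Griffin–Lim).  Unk tokens render as silence.
    """
    if dictionary.modality != "audio":
        raise ModalityError(
            f"need an audio dictionary, got {dictionary.modality!r}")
    n_fft = 512
    hop = n_fft // 4
    frames_per_window = max(1, int(round(window_s * rate_hz / hop)))
    fb = mel_filterbank(n_mels, n_fft, rate_hz)
    fb_pinv = np.linalg.pinv(fb)

    env_frames = []
    for i in ids.ids:
        if i == dictionary.unk_id:
            spec = np.zeros(n_fft // 2 + 1)
        else:
            ceps = np.zeros(n_mels)
            ceps[:n_coef] = dictionary.raw_centroids[i][:n_coef]
            log_mel = idct(ceps, type=2, norm="ortho", n=n_mels)
            mel_power = np.exp(log_mel)
            spec = np.maximum(fb_pinv @ mel_power, 0.0)
        env_frames.extend([spec] * frames_per_window)
    S = np.sqrt(np.array(env_frames).T)          # magnitude, (freq, time)
    if S.shape[1] == 0:
        return AudioTrack(np.zeros(1), rate_hz)
    if not np.any(S > 0):
        n_out = int(round(len(ids) * window_s * rate_hz))
        return AudioTrack(np.zeros(max(n_out, 1)), rate_hz)

    rng = stream(seed, "griffin-lim")
    phase = np.exp(2j * np.pi * rng.random(S.shape))
    stft_kw = dict(fs=rate_hz, nperseg=n_fft, noverlap=n_fft - hop,
                   window="hann", boundary="zeros")
    for _ in range(n_iter):
        _, x = sp_signal.istft(S * phase, **{k: v for k, v in stft_kw.items()
                                             if k != "boundary"},
                               input_onesided=True, boundary=True)
        _, _, Z = sp_signal.stft(x, **stft_kw)
        Z = Z[:, : S.shape[1]]
        if Z.shape[1] < S.shape[1]:
            Z = np.pad(Z, ((0, 0), (0, S.shape[1] - Z.shape[1])))
        mag = np.abs(Z)
        phase = np.where(mag > 0, Z / np.maximum(mag, 1e-12), phase)
    _, x = sp_signal.istft(S * phase, **{k: v for k, v in stft_kw.items()
                                         if k != "boundary"},
                           input_onesided=True, boundary=True)
    n_out = int(round(len(ids) * window_s * rate_hz))
    x = x[:n_out] if x.size >= n_out else np.pad(x, (0, n_out - x.size))
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return AudioTrack(x, rate_hz)
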