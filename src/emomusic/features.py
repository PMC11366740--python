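"""Per-window features: EEG differential entropy and audio MFCC.

Differential entropy (DE) of a band-limited Gaussian signal has the
closed form ``h = 0.5 * ln(2*pi*e*sigma^2)`` (nats), where ``sigma^2``
is the band-limited variance — the standard per-band feature in EEG
emotion work.  MFCCs are the usual mel-filterbank log-energy cepstra
(power spectrum -> mel filterbank -> log -> DCT-II).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft

#: Canonical EEG bands inside a 4-45 Hz analysis range.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (4.0, 8.0),    # theta
    (8.0, 13.0),   # alpha
    (13.0, 30.0),  # beta
    (30.0, 45.0),  # gamma
)

#: DE floor substituted for zero-variance (constant) bands.
DE_FLOOR = -20.0


@dataclass
class DEFeatureFrame:
    """Differential entropy per channel and band (nats)."""

    values: np.ndarray                     # N channels x B bands
    band_edges: tuple[tuple[float, float], ...]
    window_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != len(self.band_edges):
            raise ValueError("values/band_edges mismatch")


@dataclass
class MFCCFrame:
    values: np.ndarray
    frame_index: int
    hop_s: float


def differential_entropy(window: np.ndarray, rate_hz: float,
                         band_edges=DEFAULT_BANDS,
                         window_index: int = 0) -> DEFeatureFrame:
    """DE of each channel in each frequency band.

    Each band is isolated with a zero-phase Butterworth band-pass, the
    sample variance of the filtered signal taken, and the Gaussian
    closed form applied.  Constant (zero-variance) bands would give
    ``-inf``; they are floored at :data:`DE_FLOOR` with a warning.
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if window.shape[1] < rate_hz:
        raise ValueError("window must cover at least one second of signal")
    nyq = rate_hz / 2.0
    vals = np.empty((window.shape[0], len(band_edges)))
    for b, (lo, hi) in enumerate(band_edges):
        if not (0.0 < lo < hi < nyq):
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate_hz,
                            output="sos")
        filtered = signal.sosfiltfilt(sos, window, axis=1)
        var = filtered.var(axis=1)
        with np.errstate(divide="ignore"):
            de = 0.5 * np.log(2.0 * np.pi * np.e * var)
        if np.any(~np.isfinite(de)):
            warnings.warn("zero-variance band; DE floored", RuntimeWarning)
            de = np.where(np.isfinite(de), de, DE_FLOOR)
        vals[:, b] = np.maximum(de, DE_FLOOR)
    return DEFeatureFrame(vals, tuple(band_edges), window_index)


def flatten_de(frame: DEFeatureFrame) -> np.ndarray:
    """Row-major (channel-major) flattening: element (ch, band) -> ch*B + band."""
    return frame.values.reshape(-1).copy()


def unflatten_de(vec: np.ndarray, n_channels: int, n_bands: int) -> np.ndarray:
    return np.asarray(vec).reshape(n_channels, n_bands)


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate_hz: float,
                   f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    f_hi = rate_hz / 2.0 if f_hi is None else f_hi
    mel_pts = np.linspace(_mel(f_lo), _mel(f_hi), n_filters + 2)
    hz_pts = _mel_inv(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate_hz).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        if b > a:
            fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def mfcc(window: np.ndarray, rate_hz: float, n_coef: int = 20,
         frame_s: float = 0.025, hop_s: float = 0.010,
         n_mels: int = 40) -> list[MFCCFrame]:
    """MFCCs of a mono window over short Hamming-windowed frames.

    Frame count is ``floor((len - frame) / hop) + 1``.  Silent frames
    are floored before the log, so output is always finite.
    """
    window = np.asarray(window, dtype=np.float64).reshape(-1)
    n_frame = int(round(frame_s * rate_hz))
    n_hop = int(round(hop_s * rate_hz))
    if window.size < n_frame:
        raise ValueError("window shorter than one analysis frame")
    n_frames = (window.size - n_frame) // n_hop + 1
    n_fft = int(2 ** np.ceil(np.log2(n_frame)))
    fb = mel_filterbank(n_mels, n_fft, rate_hz)
    ham = np.hamming(n_frame)
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = window[idx] * ham
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    mel_energy = spec @ fb.T
    log_mel = np.log(np.maximum(mel_energy, 1e-10))
    ceps = dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_coef]
    return [MFCCFrame(ceps[i], i, hop_s) for i in range(n_frames)]


def mfcc_matrix(window: np.ndarray, rate_hz: float, **kwargs) -> np.ndarray:
    """MFCC frames stacked as (n_frames, n_coef)."""
    return np.stack([f.values for f in mfcc(window, rate_hz, **kwargs)])


def window_mfcc_summary(window: np.ndarray, rate_hz: float, **kwargs) -> np.ndarray:
    """Mean MFCC vector of a window — the per-token audio feature.

    The analysis window (4 s) is the token granularity for both
    modalities, so audio frames are aggregated to one vector per window
    before clustering.
    """
    return mfcc_matrix(window, rate_hz, **kwargs).mean(axis=0)


def window_de_features(seg, band_edges=DEFAULT_BANDS) -> np.ndarray:
    """Flattened DE vectors for all EEG windows of a segmented trial."""
    rows = [flatten_de(differential_entropy(w, seg.eeg_rate_hz, band_edges, i))
            for i, w in enumerate(seg.eeg_windows)]
    return np.stack(rows)


def window_audio_features(seg, **kwargs) -> np.ndarray:
    """Mean-MFCC vectors for all audio windows of a segmented trial."""
    return np.stack([window_mfcc_summary(w, seg.audio_rate_hz, **kwargs)
                     for w in seg.audio_windows])
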