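"""EEG/audio containers and preprocessing: filtering, resampling,
baseline correction, channel selection and 4-s windowing.

The processing chain mirrors standard practice for the DEAP corpus:
band-pass 4–45 Hz, resample to 128 Hz, drop the 3 s pre-stimulus
baseline (subtracting its per-channel mean), then partition the 60 s
stimulus into non-overlapping 4 s analysis windows aligned across
modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: The 32-channel DEAP electrode layout (Twente ordering).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)


class InvalidBandError(ValueError):
    """Filter band incompatible with the sampling rate."""


class ChannelNotFoundError(KeyError):
    """Requested channel names absent from the recording."""


class InvalidTrialError(ValueError):
    """Trial too short / inconsistent for the requested operation."""


@dataclass
class EEGRecording:
    """Multichannel EEG trial: ``data`` is channels x samples (µV)."""

    data: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...]
    baseline_s: float = 0.0
    subject_id: int = 0
    trial_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise InvalidTrialError("EEG data must be a non-empty channels x samples matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidTrialError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class AudioTrack:
    """Mono audio with samples in [-1, 1]."""

    data: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64).reshape(-1)
        if self.data.size < 1:
            raise InvalidTrialError("audio track is empty")

    @property
    def duration_s(self) -> float:
        return self.data.size / self.rate_hz


@dataclass
class SegmentedTrial:
    """Aligned non-overlapping EEG/audio windows of ``window_s`` seconds."""

    eeg_windows: list[np.ndarray]
    audio_windows: list[np.ndarray]
    window_s: float
    eeg_rate_hz: float
    audio_rate_hz: float
    channel_names: tuple[str, ...] = ()
    subject_id: int = 0
    trial_id: int = 0

    def __post_init__(self):
        if len(self.eeg_windows) != len(self.audio_windows):
            raise InvalidTrialError("EEG and audio window counts differ")

    @property
    def n_windows(self) -> int:
        return len(self.eeg_windows)


def bandpass_filter(rec: EEGRecording, low_hz: float = 4.0,
                    high_hz: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    The filter is run forward and backward (``sosfiltfilt``), so the
    pass band is phase-neutral and the effective order doubles.
    """
    nyq = rec.rate_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz invalid for rate {rec.rate_hz} Hz "
            f"(need 0 < low < high < Nyquist {nyq})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.rate_hz, output="sos")
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=1))


def downsample(rec: EEGRecording, target_hz: float) -> EEGRecording:
    """Resample to ``target_hz`` with anti-alias filtering (polyphase)."""
    if target_hz > rec.rate_hz:
        raise InvalidBandError(
            f"target rate {target_hz} Hz exceeds input rate {rec.rate_hz} Hz; "
            "upsampling is not supported")
    if target_hz == rec.rate_hz:
        return replace(rec)
    from fractions import Fraction
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, rate_hz=target_hz)


def remove_baseline(rec: EEGRecording) -> EEGRecording:
    """Drop the pre-stimulus baseline and subtract its per-channel mean."""
    if rec.baseline_s <= 0:
        raise InvalidTrialError("recording has no baseline period to remove")
    n_base = int(round(rec.baseline_s * rec.rate_hz))
    if n_base >= rec.n_samples:
        raise InvalidTrialError(
            f"baseline ({rec.baseline_s} s) covers the whole recording")
    mean = rec.data[:, :n_base].mean(axis=1, keepdims=True)
    return replace(rec, data=rec.data[:, n_base:] - mean, baseline_s=0.0)


def normalize_audio(track: AudioTrack) -> AudioTrack:
    """Peak-normalise to [-1, 1]; silent tracks pass through."""
    peak = np.abs(track.data).max()
    if peak == 0:
        return AudioTrack(track.data.copy(), track.rate_hz)
    return AudioTrack(track.data / peak, track.rate_hz)


def segment_windows(eeg: EEGRecording, audio: AudioTrack,
                    window_s: float = 4.0) -> SegmentedTrial:
    """Partition both modalities into aligned [t, t+window_s) windows.

    The trailing partial window is dropped; window i of each modality
    spans the same time interval.
    """
    if eeg.baseline_s > 0:
        raise InvalidTrialError("remove the baseline before segmenting")
    dur = min(eeg.duration_s, audio.duration_s)
    n_win = int(np.floor(dur / window_s + 1e-9))
    if n_win < 1:
        raise InvalidTrialError(
            f"trial of {dur:.2f} s shorter than one {window_s} s window")
    w_eeg = int(round(window_s * eeg.rate_hz))
    w_aud = int(round(window_s * audio.rate_hz))
    eeg_windows = [eeg.data[:, i * w_eeg:(i + 1) * w_eeg].copy() for i in range(n_win)]
    audio_windows = [audio.data[i * w_aud:(i + 1) * w_aud].copy() for i in range(n_win)]
    return SegmentedTrial(eeg_windows, audio_windows, window_s,
                          eeg.rate_hz, audio.rate_hz, eeg.channel_names,
                          subject_id=eeg.subject_id, trial_id=eeg.trial_id)


def select_channels(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Subset/reorder channels to ``names`` (e.g. a baseline's montage)."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise ChannelNotFoundError(
            f"channels not in recording: {', '.join(missing)}")
    idx = [rec.channel_names.index(n) for n in names]
    return replace(rec, data=rec.data[idx], channel_names=tuple(names))


#: Channel subsets used by prior EEG-to-music systems, selectable for
#: like-for-like comparisons.
CHANNEL_PRESETS: dict[str, tuple[str, ...]] = {
    "all": DEAP_CHANNELS,
    "tiraboschi": ("FC5", "FC6", "CP5", "CP6", "PO3", "PO4"),
    "inoue": ("AF3", "AF4", "T7", "T8", "Pz"),
    # PO7/PO8 from the published 29-channel montage are absent from the
    # 32-channel DEAP layout, so the preset keeps the 27 available ones.
    "miyamoto": ("Fp1", "Fp2", "AF3", "AF4", "F7", "F8", "F3", "Fz", "F4",
                 "FC5", "FC6", "T7", "T8", "C3", "Cz", "C4", "CP5", "CP6",
                 "P7", "P8", "P3", "Pz", "P4", "PO3", "PO4", "O1", "O2"),
}
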