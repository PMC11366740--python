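"""Coupled synthetic EEG/audio trials driven by a latent emotional state.

Real EEG-to-music corpora pair each subject's multichannel EEG with the
music stimulus that evoked it; the learnable signal is the shared
emotional content.  This module emulates that structure: a first-order
Markov chain over ``K`` emotional states emits, per 4-s frame,

* an EEG template — a band-limited oscillation (one canonical EEG band
  per state: theta/alpha/beta/gamma) with fixed per-channel loadings —
  plus white noise, and
* an audio template — a state-specific harmonic stack — plus noise.

Both modalities are driven by the *same* state sequence, so the
EEG-to-audio-token mapping downstream is learnable and its recovery
testable.  Templates are shared across subjects (subjects differ by
noise realisation and a small gain factor), keeping cross-subject
generalisation well-posed.  All randomness flows from ``cfg.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from ._rng import stream
from .preproc import DEAP_CHANNELS, AudioTrack, EEGRecording

#: State -> (low_hz, high_hz) template band, matching canonical EEG bands.
STATE_BANDS: tuple[tuple[float, float], ...] = (
    (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 45.0))

#: State -> audio fundamental (Hz); harmonic stacks sit on these roots.
STATE_FUNDAMENTALS: tuple[float, ...] = (220.0, 277.18, 329.63, 440.0)


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for fixture generation (DEAP-like shape)."""

    n_subjects: int = 5
    n_trials: int = 3
    n_channels: int = 32
    eeg_rate_hz: float = 128.0
    audio_rate_hz: float = 8000.0
    trial_s: float = 60.0
    baseline_s: float = 3.0
    K: int = 4
    seed: int = 0
    noise_sd: float = 0.3
    transition_stay_prob: float = 0.9
    frame_duration_s: float = 4.0

    def __post_init__(self):
        if min(self.n_subjects, self.n_trials, self.n_channels, self.K) < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.eeg_rate_hz <= 0 or self.audio_rate_hz <= 0:
            raise InvalidConfigError("sampling rates must be positive")
        if self.baseline_s < 0 or self.trial_s <= 0:
            raise InvalidConfigError("durations invalid")
        if not 0.0 <= self.transition_stay_prob <= 1.0:
            raise InvalidConfigError("transition_stay_prob must be in [0, 1]")
        if self.K > len(STATE_BANDS):
            raise InvalidConfigError(
                f"K <= {len(STATE_BANDS)} states supported by the template bank")


@dataclass(frozen=True)
class LatentStateSequence:
    """Per-frame emotional states, one per ``frame_duration_s`` seconds."""

    states: np.ndarray
    K: int
    transition_stay_prob: float
    frame_duration_s: float

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int64))
        if self.states.size < 1:
            raise InvalidConfigError("latent sequence must have >= 1 frame")
        if self.states.min() < 0 or self.states.max() >= self.K:
            raise InvalidConfigError("states out of range")

    def __len__(self):
        return self.states.size


def gen_latent_states(cfg: SynthConfig, n_frames: int | None = None,
                      rng: np.random.Generator | None = None) -> LatentStateSequence:
    """Sample a Markov chain over K states with uniform off-diagonal moves."""
    if n_frames is None:
        n_frames = int(np.ceil(cfg.trial_s / cfg.frame_duration_s))
    rng = rng if rng is not None else stream(cfg.seed, "latent")
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = rng.integers(cfg.K)
    for t in range(1, n_frames):
        if cfg.K == 1 or rng.random() < cfg.transition_stay_prob:
            states[t] = states[t - 1]
        else:
            move = rng.integers(cfg.K - 1)
            states[t] = move + (move >= states[t - 1])
    return LatentStateSequence(states, cfg.K, cfg.transition_stay_prob,
                               cfg.frame_duration_s)


def _templates(cfg: SynthConfig):
    """Fixed per-state channel loadings and audio harmonic weights."""
    rng = stream(cfg.seed, "templates")
    loadings = 0.5 + rng.random((cfg.K, cfg.n_channels))          # in [0.5, 1.5)
    freqs = np.array([np.mean(STATE_BANDS[k]) for k in range(cfg.K)])
    harm_w = 1.0 / (1.0 + np.arange(5))                           # 1/n rolloff
    phases = rng.uniform(0, 2 * np.pi, (cfg.K, cfg.n_channels))
    return loadings, freqs, harm_w, phases


def gen_coupled_pair(cfg: SynthConfig, latent: LatentStateSequence,
                     subject_id: int = 0, trial_id: int = 0
                     ) -> tuple[EEGRecording, AudioTrack]:
    """Render one EEG trial (baseline + stimulus) and its paired audio."""
    n_frames_needed = int(np.ceil(cfg.trial_s / cfg.frame_duration_s))
    if len(latent) < n_frames_needed:
        raise InvalidConfigError(
            f"latent sequence of {len(latent)} frames cannot cover "
            f"{cfg.trial_s} s at {cfg.frame_duration_s} s/frame")
    rng = stream(cfg.seed, "pair", subject_id, trial_id)
    loadings, freqs, harm_w, phases = _templates(cfg)
    gain = 1.0 + 0.1 * (stream(cfg.seed, "subject", subject_id).random() - 0.5)

    n_eeg = int(round((cfg.baseline_s + cfg.trial_s) * cfg.eeg_rate_hz))
    n_base = int(round(cfg.baseline_s * cfg.eeg_rate_hz))
    eeg = rng.normal(0.0, cfg.noise_sd, (cfg.n_channels, n_eeg))

    w_eeg = int(round(cfg.frame_duration_s * cfg.eeg_rate_hz))
    t_frame = np.arange(w_eeg) / cfg.eeg_rate_hz
    for i in range(n_frames_needed):
        s = int(latent.states[i])
        start = n_base + i * w_eeg
        stop = min(start + w_eeg, n_eeg)
        seg = t_frame[: stop - start]
        osc = np.sin(2 * np.pi * freqs[s] * seg[None, :] + phases[s][:, None])
        eeg[:, start:stop] += gain * loadings[s][:, None] * osc

    n_aud = int(round(cfg.trial_s * cfg.audio_rate_hz))
    audio = rng.normal(0.0, cfg.noise_sd * 0.1, n_aud)
    w_aud = int(round(cfg.frame_duration_s * cfg.audio_rate_hz))
    t_aud = np.arange(w_aud) / cfg.audio_rate_hz
    env = np.minimum(1.0, np.minimum(np.arange(w_aud), np.arange(w_aud)[::-1])
                     / (0.01 * cfg.audio_rate_hz + 1))            # click-free edges
    for i in range(n_frames_needed):
        s = int(latent.states[i])
        start = i * w_aud
        stop = min(start + w_aud, n_aud)
        seg = t_aud[: stop - start]
        # two-bar alternation: odd windows voice the chord a fifth up,
        # so each emotional state owns two distinct timbres (2K total)
        f0 = STATE_FUNDAMENTALS[s] * (1.5 if i % 2 else 1.0)
        tone = sum(w * np.sin(2 * np.pi * f0 * (h + 1) * seg)
                   for h, w in enumerate(harm_w))
        audio[start:stop] += 0.3 * env[: stop - start] * tone

    peak = np.abs(audio).max()
    if peak > 1.0:
        audio = audio / peak
    rec = EEGRecording(eeg, cfg.eeg_rate_hz,
                       tuple(DEAP_CHANNELS[: cfg.n_channels]),
                       baseline_s=cfg.baseline_s,
                       subject_id=subject_id, trial_id=trial_id)
    return rec, AudioTrack(audio, cfg.audio_rate_hz)


def gen_dataset(cfg: SynthConfig):
    """All (subject, trial) pairs with their latent sequences.

    Returns a list of dicts with keys subject_id, trial_id, latent, eeg,
    audio.  Each trial draws its own latent chain from a seeded stream.
    """
    out = []
    for subj in range(cfg.n_subjects):
        for trial in range(cfg.n_trials):
            latent = gen_latent_states(
                cfg, rng=stream(cfg.seed, "latent", subj, trial))
            eeg, audio = gen_coupled_pair(cfg, latent, subj, trial)
            out.append({"subject_id": subj, "trial_id": trial,
                        "latent": latent, "eeg": eeg, "audio": audio})
    return out


def write_fixture(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Generate the dataset and write it to disk; returns the manifest path.

    Layout: per trial ``sXX_tYY_eeg.npy`` + JSON sidecar, 16-bit PCM WAV
    audio, and a top-level ``manifest.json`` listing files, rates and
    latent states.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in gen_dataset(cfg):
        tag = f"s{rec['subject_id']:02d}_t{rec['trial_id']:02d}"
        eeg_path = out_dir / f"{tag}_eeg.npy"
        np.save(eeg_path, rec["eeg"].data)
        meta = {"rate_hz": rec["eeg"].rate_hz,
                "channel_names": list(rec["eeg"].channel_names),
                "baseline_s": rec["eeg"].baseline_s}
        (out_dir / f"{tag}_eeg.json").write_text(json.dumps(meta, indent=1))
        wav_path = out_dir / f"{tag}_audio.wav"
        pcm = np.clip(rec["audio"].data, -1.0, 1.0)
        wavfile.write(wav_path, int(cfg.audio_rate_hz),
                      (pcm * 32767).astype(np.int16))
        entries.append({"subject_id": rec["subject_id"],
                        "trial_id": rec["trial_id"],
                        "eeg": eeg_path.name, "eeg_meta": f"{tag}_eeg.json",
                        "audio": wav_path.name,
                        "latent_states": rec["latent"].states.tolist()})
    manifest = {"config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
                "trials": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_fixture(manifest_path: str | Path):
    """Read back a fixture written by :func:`write_fixture`."""
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    cfg = SynthConfig(**man["config"])
    out = []
    for e in man["trials"]:
        meta = json.loads((root / e["eeg_meta"]).read_text())
        eeg = EEGRecording(np.load(root / e["eeg"]), meta["rate_hz"],
                           tuple(meta["channel_names"]),
                           baseline_s=meta["baseline_s"],
                           subject_id=e["subject_id"], trial_id=e["trial_id"])
        rate, pcm = wavfile.read(root / e["audio"])
        audio = AudioTrack(pcm.astype(np.float64) / 32767.0, float(rate))
        latent = LatentStateSequence(np.array(e["latent_states"]), cfg.K,
                                     cfg.transition_stay_prob,
                                     cfg.frame_duration_s)
        out.append({"subject_id": e["subject_id"], "trial_id": e["trial_id"],
                    "latent": latent, "eeg": eeg, "audio": audio})
    return cfg, out
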