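"""Synthetic multi-channel sEMG envelope generator.

Emulates RMS-rectified, low-rate envelope recordings with a controllable
class structure: each gesture owns a fixed channel-activation weight vector
(distinct across gestures), each repetition is a sum of smooth Gaussian
activation bursts with per-repetition amplitude jitter, and folded Gaussian
noise is added at a configurable SNR.  Outputs are non-negative, like
rectified envelopes, and every (subject, gesture, repetition) triple yields
one labeled :class:`~semgimg.windows.Recording`.

This is a statistical stand-in for benchmark recordings, not a biophysical
simulation: it carries a learnable, channel-pattern class signal but none
of the electrode-shift, fatigue, or crosstalk structure of real sEMG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import save_recording_mat
from .windows import ConfigurationError, Recording

__all__ = ["SynthConfig", "gesture_weights", "generate", "export_ninapro_style"]

# minimum recording length in samples; one canonical 200 ms window at 100 Hz
_MIN_SAMPLES = 20


@dataclass(frozen=True)
class SynthConfig:
    """Generator condition set.

    Defaults mirror the benchmark acquisition they emulate: 10 electrode
    channels at 100 Hz, 5 s per repetition, 10 repetitions per gesture.
    ``snr_db`` is the ratio of clean-envelope RMS to noise standard
    deviation, in dB.
    """

    subjects: int = 27
    gestures: int = 52
    repetitions: int = 10
    channels: int = 10
    fs: float = 100.0
    duration_s: float = 5.0
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subjects", "gestures", "repetitions", "channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        if self.duration_s * self.fs < _MIN_SAMPLES:
            raise ConfigurationError(
                f"duration of {self.duration_s} s at {self.fs} Hz yields fewer "
                f"than {_MIN_SAMPLES} samples; too short to window"
            )

    @classmethod
    def armband(cls, **overrides) -> "SynthConfig":
        """8-channel, 500 Hz arm-band preset (6 gestures, 30 repetitions)."""
        defaults = dict(subjects=5, gestures=6, repetitions=30, channels=8,
                        fs=500.0, duration_s=5.0)
        defaults.update(overrides)
        return cls(**defaults)


def gesture_weights(n_gestures: int, n_channels: int,
                    rng: np.random.Generator,
                    max_cosine: float = 0.95,
                    max_tries: int = 500) -> np.ndarray:
    """Draw one non-negative activation weight vector per gesture.

    Vectors are redrawn until every pair is separated in angle
    (pairwise cosine similarity below ``max_cosine``), so no two gestures
    share a channel-activation pattern.
    """
    w = np.abs(rng.normal(0.0, 1.0, size=(n_gestures, n_channels))) + 0.1
    for _ in range(max_tries):
        unit = w / np.linalg.norm(w, axis=1, keepdims=True)
        cos = unit @ unit.T
        np.fill_diagonal(cos, 0.0)
        bad = np.unique(np.argwhere(cos > max_cosine)[:, 0])
        if bad.size == 0:
            return w
        w[bad] = np.abs(rng.normal(0.0, 1.0, size=(bad.size, n_channels))) + 0.1
    raise ConfigurationError(
        "could not draw sufficiently distinct gesture weight vectors; "
        "reduce gestures or raise max_cosine"
    )


def _burst_envelope(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of 2-4 Gaussian activation bursts within the repetition."""
    duration = t[-1] if t.size else 0.0
    n_bursts = int(rng.integers(2, 5))
    env = np.zeros_like(t)
    for _ in range(n_bursts):
        center = rng.uniform(0.1 * duration, 0.9 * duration)
        width = rng.uniform(0.5, 2.0)  # seconds, full width at ~half max
        sigma = width / 2.355
        amp = rng.uniform(0.5, 1.0)
        env += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return env


def generate(config: SynthConfig) -> list[Recording]:
    """Generate one recording per (subject, gesture, repetition) triple.

    Deterministic for a fixed config (all randomness flows from
    ``config.seed``); every sample is non-negative.
    """
    rng = np.random.default_rng(config.seed)
    weights = gesture_weights(config.gestures, config.channels, rng)
    subject_gain = rng.lognormal(0.0, 0.15, size=config.subjects)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    noise_scale = 10.0 ** (-config.snr_db / 20.0)
    recordings = []
    for s in range(config.subjects):
        for g in range(config.gestures):
            for r in range(config.repetitions):
                env = _burst_envelope(t, rng)
                rep_jitter = rng.lognormal(0.0, 0.1)
                clean = (env[:, None] * weights[g][None, :]) * (
                    subject_gain[s] * rep_jitter
                )
                rms = np.sqrt(np.mean(clean**2))
                noise = np.abs(rng.normal(0.0, rms * noise_scale + 1e-12,
                                          size=clean.shape))
                recordings.append(
                    Recording(signal=clean + noise, fs=config.fs,
                              subject=s + 1, stimulus=g + 1, repetition=r + 1)
                )
    return recordings


def export_ninapro_style(recordings: list[Recording],
                         out_dir: str | Path) -> list[Path]:
    """Write one `SSS_GGG_RRR.mat` file per recording into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        name = f"{rec.subject:03d}_{rec.stimulus:03d}_{rec.repetition:03d}.mat"
        paths.append(save_recording_mat(rec, out_dir / name))
    return paths
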