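"""Windowed segmentation and preprocessing of multi-channel sEMG recordings.

A :class:`Recording` holds a samples x channels envelope matrix together with
its sampling rate and (subject, stimulus, repetition) provenance.  The
operations here cut recordings into fixed-length sliding windows, denoise
them channel-wise with a discrete wavelet transform, and downsample them by
integer factors with anti-alias filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _sig

__all__ = [
    "Recording",
    "WindowSpec",
    "SignalWindow",
    "ConfigurationError",
    "sliding_windows",
    "wavelet_denoise",
    "downsample",
]


class ConfigurationError(ValueError):
    """Raised when a processing step is configured inconsistently."""


@dataclass(frozen=True)
class Recording:
    """A multi-channel envelope recording with provenance labels.

    Parameters
    ----------
    signal : ndarray of shape (n_samples, n_channels)
        Envelope amplitudes; one column per electrode channel.
    fs : float
        Sampling rate in Hz.
    subject, stimulus, repetition : int
        Provenance identifiers.  ``stimulus`` is the gesture label.
    """

    signal: np.ndarray
    fs: float
    subject: int = 1
    stimulus: int = 0
    repetition: int = 1

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.ndim != 2 or sig.shape[1] < 1:
            raise ValueError("signal must be a 2-D samples x channels matrix")
        if not np.isfinite(sig).all():
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds.

    ``tw_ms`` is the window length and ``ts_ms`` the stride.  Sample counts
    are derived per recording as ``round(ms * fs / 1000)``; at 100 Hz the
    default 200/100 ms resolves to 20/10 samples.
    """

    tw_ms: float = 200.0
    ts_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.tw_ms <= 0 or self.ts_ms <= 0:
            raise ConfigurationError("window length and stride must be positive")

    def samples(self, fs: float) -> tuple[int, int]:
        """Return (tw, ts) in samples for sampling rate ``fs``."""
        tw = int(round(self.tw_ms * fs / 1000.0))
        ts = int(round(self.ts_ms * fs / 1000.0))
        if tw < 1 or ts < 1:
            raise ConfigurationError(
                f"window spec {self.tw_ms}/{self.ts_ms} ms resolves to "
                f"tw={tw}, ts={ts} samples at fs={fs} Hz; both must be >= 1"
            )
        return tw, ts


@dataclass(frozen=True)
class SignalWindow:
    """One fixed-length slice of a recording carrying its gesture label."""

    data: np.ndarray  # (tw, C)
    label: int
    subject: int = 1
    repetition: int = 1
    start_index: int = 0

    @property
    def tw(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def sliding_windows(rec: Recording, spec: WindowSpec) -> list[SignalWindow]:
    """Cut ``rec`` into complete sliding windows at offsets 0, ts, 2*ts, ...

    Only full windows are emitted; an incomplete tail is dropped.  Each
    window inherits the recording's stimulus label and provenance.
    """
    tw, ts = spec.samples(rec.fs)
    n = rec.n_samples
    if n < tw:
        return []
    # strided view over time, then strided again over window starts
    views = sliding_window_view(rec.signal, tw, axis=0)[::ts]  # (k, C, tw)
    out = []
    for i, v in enumerate(views):
        out.append(
            SignalWindow(
                data=np.ascontiguousarray(v.T),
                label=rec.stimulus,
                subject=rec.subject,
                repetition=rec.repetition,
                start_index=i * ts,
            )
        )
    return out


def _universal_soft_threshold(coeffs: list[np.ndarray]) -> list[np.ndarray]:
    # VisuShrink: sigma from the median absolute deviation of the finest
    # detail band, threshold sigma * sqrt(2 log n) applied softly to all
    # detail bands.
    n = sum(c.size for c in coeffs)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    if thr <= 0.0:  # noiseless channel: nothing to shrink
        return coeffs
    out = [coeffs[0]]
    for c in coeffs[1:]:
        out.append(pywt.threshold(c, thr, mode="soft"))
    return out


def wavelet_denoise(
    rec: Recording,
    wavelet_name: str = "db4",
    level: int = 4,
    threshold_rule: str = "universal-soft",
) -> Recording:
    """Denoise each channel independently with a wavelet shrinkage filter.

    Each channel is decomposed to ``level`` scales, the detail coefficients
    are soft-thresholded (universal / VisuShrink rule), and the channel is
    reconstructed to its original length.
    """
    if threshold_rule != "universal-soft":
        raise ConfigurationError(f"unknown threshold rule: {threshold_rule!r}")
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet: {wavelet_name!r}") from exc
    n = rec.n_samples
    if level < 1:
        raise ConfigurationError("decomposition level must be >= 1")
    if n < 2**level:
        raise ConfigurationError(
            f"signal of {n} samples too short for level-{level} decomposition"
        )
    out = np.empty_like(rec.signal)
    for c in range(rec.n_channels):
        coeffs = pywt.wavedec(rec.signal[:, c], wavelet, level=level)
        coeffs = _universal_soft_threshold(coeffs)
        recon = pywt.waverec(coeffs, wavelet)
        out[:, c] = recon[:n]
    return replace(rec, signal=out)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Decimate ``rec`` to ``target_fs`` with an anti-alias FIR filter.

    The source rate must be an integer multiple of the target rate.  A
    zero-phase FIR low-pass is applied before keeping every ``factor``-th
    sample, so constants survive and no phase shift is introduced.
    """
    if target_fs <= 0:
        raise ConfigurationError("target_fs must be positive")
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"fs={rec.fs} is not an integer multiple of target_fs={target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return replace(rec, fs=float(target_fs))
    out = _sig.decimate(rec.signal, factor, axis=0, ftype="fir", zero_phase=True)
    return replace(rec, signal=out, fs=float(target_fs))
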