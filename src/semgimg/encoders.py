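"""Image encodings for sEMG windows: Sigimg, GADF, and MTF.

A window of ``tw`` samples over ``C`` channels is mapped to three 2-D
images:

* **Sigimg** — the window tiled horizontally as ``C`` cyclic column
  rotations of itself (``tw x C^2``), so 2-D convolutions can see
  cross-channel structure;
* **GADF** — each channel min-max rescaled to [-1, 1], mapped to polar
  angles ``phi_i = arccos(x~_i)``, and expanded into the Gramian matrix
  ``G[i, j] = cos(phi_i - phi_j)`` (``tw x tw`` per channel, stitched to
  ``tw x (C*tw)``);
* **MTF** — each channel quantile-binned into ``Q`` states, a first-order
  Markov transition matrix ``W`` estimated from consecutive samples, and
  the field ``M[i, j] = W[bin(x_i), bin(x_j)]`` laid out chronologically
  (stitched like GADF).

All three images are min-max normalized to [0, 1] per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .windows import ConfigurationError, SignalWindow

__all__ = [
    "RescaledSeries",
    "PolarSeries",
    "TransitionMatrix",
    "EncodedSample",
    "rescale_unit",
    "to_polar",
    "gadf",
    "mtf_bins",
    "mtf_transition",
    "mtf_field",
    "mtf",
    "sigimg",
    "stitch_subimages",
    "normalize_image",
    "encode_window",
    "WindowImageEncoder",
]

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class RescaledSeries:
    """A series rescaled to [-1, 1] by the two-sided min-max map."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


@dataclass(frozen=True)
class PolarSeries:
    """Polar representation: angles in [0, pi] and radii ``t_i / N``."""

    angles: np.ndarray
    radii: np.ndarray


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic Q x Q Markov transition matrix with its bin edges."""

    W: np.ndarray
    q: int
    bin_edges: np.ndarray


@dataclass(frozen=True)
class EncodedSample:
    """The (sigimg, gadf, mtf) image triple for one window, normalized."""

    sigimg: np.ndarray  # (tw, C*C)
    gadf: np.ndarray  # (tw, C*tw)
    mtf: np.ndarray  # (tw, C*tw)
    label: int
    subject: int = 1
    repetition: int = 1
    start_index: int = 0


def rescale_unit(series: np.ndarray) -> RescaledSeries:
    """Rescale a series to [-1, 1].

    Uses the two-sided map ``x~ = ((x - max) + (x - min)) / (max - min)``,
    which sends the minimum to -1 and the maximum to +1.  A constant series
    has zero range and maps to all zeros (the midpoint).
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot rescale an empty series")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return RescaledSeries(np.zeros_like(x))
    return RescaledSeries(((x - hi) + (x - lo)) / (hi - lo))


def to_polar(rs: RescaledSeries) -> PolarSeries:
    """Map a [-1, 1] series to polar angles ``arccos(x~_i)`` in [0, pi].

    Radii are the normalized timestamps ``t_i / N`` with 1-based ``t_i``
    and ``N = n``; they are carried for completeness but the Gramian uses
    only the angles.
    """
    x = np.asarray(rs.values, dtype=np.float64)
    if np.any(np.abs(x) > 1.0 + _CLIP_TOL):
        raise ValueError("rescaled values must lie in [-1, 1]")
    angles = np.arccos(np.clip(x, -1.0, 1.0))
    n = x.size
    radii = np.arange(1, n + 1, dtype=np.float64) / n
    return PolarSeries(angles=angles, radii=radii)


def gadf(ps: PolarSeries, formula: str = "cos_diff") -> np.ndarray:
    """Gramian angular difference field ``G[i, j] = f(phi_i - phi_j)``.

    ``formula='cos_diff'`` (default) uses the cosine of the angle
    difference, giving a symmetric matrix with unit diagonal;
    ``'sin_diff'`` uses the sine form common elsewhere in the
    time-series-imaging literature, giving an antisymmetric matrix.
    """
    phi = np.asarray(ps.angles, dtype=np.float64)
    diff = phi[:, None] - phi[None, :]
    if formula == "cos_diff":
        return np.cos(diff)
    if formula == "sin_diff":
        return np.sin(diff)
    raise ConfigurationError(f"unknown gadf formula: {formula!r}")


def mtf_bins(series: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each sample to one of ``q`` empirical quantile bins.

    Returns ``(bins, bin_edges)`` where ``bins[i]`` is in ``0..q-1`` and
    ``bin_edges`` holds the ``q+1`` ascending quantile edges.  Intervals
    are half-open on the right; the last interval is closed.
    """
    if q < 2:
        raise ConfigurationError("Q must be >= 2")
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples to bin")
    edges = np.quantile(x, np.linspace(0.0, 1.0, q + 1))
    bins = np.searchsorted(edges[1:-1], x, side="right")
    return bins.astype(np.intp), edges


def mtf_transition(
    bins: np.ndarray, q: int, bin_edges: np.ndarray | None = None
) -> TransitionMatrix:
    """Estimate the row-stochastic transition matrix from a bin sequence.

    ``W[a, b]`` is the fraction of consecutive pairs that move from bin
    ``a`` to bin ``b``.  Bins with no outgoing transition get the uniform
    row ``1/q`` so every row sums to one.
    """
    b = np.asarray(bins, dtype=np.intp).ravel()
    if b.size < 2:
        raise ValueError("need at least 2 samples to estimate transitions")
    counts = np.zeros((q, q), dtype=np.float64)
    np.add.at(counts, (b[:-1], b[1:]), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    W = np.where(row > 0, counts / np.where(row > 0, row, 1.0), 1.0 / q)
    if bin_edges is None:
        bin_edges = np.full(q + 1, np.nan)
    return TransitionMatrix(W=W, q=q, bin_edges=np.asarray(bin_edges, dtype=np.float64))


def mtf_field(bins: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Lay the transition probabilities out chronologically.

    ``M[i, j] = W[bin(x_i), bin(x_j)]`` for every sample pair, giving an
    ``n x n`` field aligned with the time axis on both sides.
    """
    b = np.asarray(bins, dtype=np.intp).ravel()
    W = np.asarray(W, dtype=np.float64)
    return W[np.ix_(b, b)]


def mtf(series: np.ndarray, q: int) -> np.ndarray:
    """Full per-channel MTF: quantile-bin, estimate W, expand to the field."""
    bins, edges = mtf_bins(series, q)
    tm = mtf_transition(bins, q, bin_edges=edges)
    return mtf_field(bins, tm.W)


def sigimg(window: SignalWindow | np.ndarray) -> np.ndarray:
    """Channel-rearrangement image: C cyclic column rotations side by side.

    Block ``k`` (k = 0..C-1) is the window with its columns rotated
    cyclically by ``k``; block 0 is the original window, so the output is
    ``tw x C^2`` and contains every channel column exactly C times.
    """
    data = window.data if isinstance(window, SignalWindow) else np.asarray(window)
    if data.ndim != 2 or data.shape[1] < 1:
        raise ValueError("window must be a tw x C matrix with C >= 1")
    C = data.shape[1]
    blocks = [np.roll(data, -k, axis=1) for k in range(C)]
    return np.concatenate(blocks, axis=1)


def stitch_subimages(subimages: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-channel n x n subimages horizontally, in channel order."""
    if not subimages:
        raise ValueError("need at least one subimage")
    mats = [np.asarray(s, dtype=np.float64) for s in subimages]
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError(
                f"all subimages must be square {n}x{n}; got {m.shape}"
            )
    return np.concatenate(mats, axis=1)


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Min-max normalize an image to [0, 1]; constant images map to 0."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def encode_window(
    window: SignalWindow,
    q: int = 8,
    gadf_formula: str = "cos_diff",
    normalize: bool = True,
) -> EncodedSample:
    """Encode one window into its (sigimg, gadf, mtf) image triple.

    The Sigimg tiling uses the raw window; the GADF and MTF encodings are
    computed per channel — each channel is rescaled to [-1, 1] within this
    window, so the encodings are self-contained — and stitched
    horizontally.  Each image is then min-max normalized to [0, 1].
    """
    data = window.data
    gadf_subs = []
    mtf_subs = []
    for c in range(data.shape[1]):
        col = data[:, c]
        gadf_subs.append(gadf(to_polar(rescale_unit(col)), formula=gadf_formula))
        mtf_subs.append(mtf(col, q))
    img_sig = sigimg(window)
    img_gadf = stitch_subimages(gadf_subs)
    img_mtf = stitch_subimages(mtf_subs)
    if normalize:
        img_sig = normalize_image(img_sig)
        img_gadf = normalize_image(img_gadf)
        img_mtf = normalize_image(img_mtf)
    return EncodedSample(
        sigimg=img_sig,
        gadf=img_gadf,
        mtf=img_mtf,
        label=window.label,
        subject=window.subject,
        repetition=window.repetition,
        start_index=window.start_index,
    )


class WindowImageEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping raw windows to flattened image-triple features.

    Accepts ``X`` of shape ``(n_windows, tw, C)`` and returns a float32
    array of shape ``(n_windows, tw*C^2 + 2*tw*C*tw)`` holding the
    flattened ``[sigimg | gadf | mtf]`` images per window.  The encoding is
    stateless; ``fit`` only records the window geometry.

    Parameters
    ----------
    q : int, default 8
        Number of quantile bins for the MTF encoding.
    gadf_formula : {'cos_diff', 'sin_diff'}, default 'cos_diff'
        Gramian angle-difference form.
    """

    def __init__(self, q: int = 8, gadf_formula: str = "cos_diff"):
        self.q = q
        self.gadf_formula = gadf_formula

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_windows, tw, C)")
        self.tw_ = X.shape[1]
        self.n_channels_ = X.shape[2]
        tw, C = self.tw_, self.n_channels_
        self.image_shapes_ = {
            "sigimg": (tw, C * C),
            "gadf": (tw, C * tw),
            "mtf": (tw, C * tw),
        }
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_windows, tw, C)")
        out = []
        for w in X:
            enc = encode_window(
                SignalWindow(data=w, label=0),
                q=self.q,
                gadf_formula=self.gadf_formula,
            )
            out.append(
                np.concatenate(
                    [enc.sigimg.ravel(), enc.gadf.ravel(), enc.mtf.ravel()]
                )
            )
        return np.asarray(out, dtype=np.float32)
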