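"""Dataset assembly: discover segmented recordings, window + encode them,
and split into train/test image datasets by repetition index.

The benchmark protocol trains on repetitions {1, 3, 4, 5, 6, 8, 9, 10} and
tests on {2, 7} — a 4:1 repetition-wise split that keeps every window of a
movement execution on one side of the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import encode_window
from .io import load_recording_mat, parse_segmented_name
from .windows import ConfigurationError, Recording, WindowSpec, sliding_windows

__all__ = [
    "SplitSpec",
    "RecordingRef",
    "EncodedDataset",
    "discover_recordings",
    "build_dataset",
    "DEFAULT_DB1_SPLIT",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test repetition index sets."""

    train_repetitions: frozenset[int]
    test_repetitions: frozenset[int]

    def __init__(self, train_repetitions, test_repetitions):
        train = frozenset(int(r) for r in train_repetitions)
        test = frozenset(int(r) for r in test_repetitions)
        if not train or not test:
            raise ConfigurationError("both split sides must be non-empty")
        if train & test:
            raise ConfigurationError(
                f"train/test repetitions overlap: {sorted(train & test)}"
            )
        object.__setattr__(self, "train_repetitions", train)
        object.__setattr__(self, "test_repetitions", test)

    def side(self, repetition: int) -> str:
        if repetition in self.train_repetitions:
            return "train"
        if repetition in self.test_repetitions:
            return "test"
        raise ConfigurationError(
            f"repetition {repetition} belongs to neither split side"
        )


DEFAULT_DB1_SPLIT = SplitSpec(train_repetitions={1, 3, 4, 5, 6, 8, 9, 10},
                              test_repetitions={2, 7})


@dataclass(frozen=True)
class RecordingRef:
    """Lazy handle on a segmented recording file with parsed provenance."""

    path: Path
    subject: int
    stimulus: int
    repetition: int

    def load(self, fs: float = 100.0) -> Recording:
        return load_recording_mat(self.path, fs=fs, subject=self.subject,
                                  stimulus=self.stimulus,
                                  repetition=self.repetition)


def discover_recordings(root_path: str | Path) -> list[RecordingRef]:
    """Scan a directory for `SSS_GGG_RRR.mat` segmented recordings.

    Malformed `.mat` filenames are reported with a warning rather than
    silently skipped; an empty directory yields an empty list with a
    warning.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise OSError(f"not a directory: {root}")
    refs = []
    malformed = []
    for path in sorted(root.glob("*.mat")):
        parsed = parse_segmented_name(path.name)
        if parsed is None:
            malformed.append(path.name)
            continue
        subject, stimulus, repetition = parsed
        refs.append(RecordingRef(path=path, subject=subject,
                                 stimulus=stimulus, repetition=repetition))
    if malformed:
        warnings.warn(
            "malformed segmented-recording filenames ignored: "
            + ", ".join(malformed),
            stacklevel=2,
        )
    if not refs:
        logger.warning("no segmented recordings found under %s", root)
    return refs


@dataclass
class EncodedDataset:
    """Encoded image dataset: per-stream image stacks plus provenance.

    ``images`` maps stream name -> float32 array of shape (n, H, W);
    ``labels`` are contiguous 0-based class indices (``class_map`` maps the
    original stimulus labels onto them).
    """

    images: dict[str, np.ndarray]
    labels: np.ndarray
    subjects: np.ndarray
    repetitions: np.ndarray
    start_indices: np.ndarray
    class_count: int
    class_map: dict[int, int]
    attrs: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def manifest(self) -> pd.DataFrame:
        inverse = {v: k for k, v in self.class_map.items()}
        return pd.DataFrame(
            {
                "subject": self.subjects,
                "stimulus": [inverse[int(l)] for l in self.labels],
                "label": self.labels,
                "repetition": self.repetitions,
                "start_index": self.start_indices,
            }
        )

    def streams(self, names: tuple[str, ...]) -> list[np.ndarray]:
        """Image stacks for the requested streams, with a trailing channel axis."""
        return [np.asarray(self.images[n], dtype=np.float32)[..., None]
                for n in names]

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            images={k: v[idx] for k, v in self.images.items()},
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            repetitions=self.repetitions[idx],
            start_indices=self.start_indices[idx],
            class_count=self.class_count,
            class_map=self.class_map,
            attrs=dict(self.attrs),
        )


def _assemble(samples: list, class_map: dict[int, int], class_count: int,
              attrs: dict) -> EncodedDataset:
    # canonical provenance order makes assembly independent of discovery order
    samples.sort(key=lambda e: (e.subject, e.label, e.repetition, e.start_index))
    if samples:
        images = {
            stream: np.stack([getattr(e, stream) for e in samples]).astype(np.float32)
            for stream in ("sigimg", "gadf", "mtf")
        }
        labels = np.array([class_map[e.label] for e in samples], dtype=np.int64)
        subjects = np.array([e.subject for e in samples], dtype=np.int64)
        repetitions = np.array([e.repetition for e in samples], dtype=np.int64)
        starts = np.array([e.start_index for e in samples], dtype=np.int64)
    else:
        images = {s: np.zeros((0, 1, 1), np.float32) for s in ("sigimg", "gadf", "mtf")}
        labels = subjects = repetitions = starts = np.zeros(0, np.int64)
    return EncodedDataset(images=images, labels=labels, subjects=subjects,
                          repetitions=repetitions, start_indices=starts,
                          class_count=class_count, class_map=class_map,
                          attrs=attrs)


def encode_recordings(
    recordings,
    window_spec: WindowSpec,
    q: int = 8,
    gadf_formula: str = "cos_diff",
) -> EncodedDataset:
    """Window and encode recordings into one image dataset (no split).

    ``recordings`` may hold :class:`~semgimg.windows.Recording` objects or
    :class:`RecordingRef` handles (loaded on demand).  Stimulus labels are
    remapped to contiguous 0-based class indices; the mapping is recorded
    on the dataset.  Samples are returned in canonical provenance order, so
    the result is independent of discovery order.
    """
    recs = []
    for item in recordings:
        recs.append(item.load() if isinstance(item, RecordingRef) else item)
    if not recs:
        raise ConfigurationError("no recordings to build a dataset from")
    stimuli = sorted({r.stimulus for r in recs})
    class_map = {int(s): i for i, s in enumerate(stimuli)}
    samples = []
    attrs: dict = {}
    for rec in recs:
        for window in sliding_windows(rec, window_spec):
            samples.append(encode_window(window, q=q, gadf_formula=gadf_formula))
        if not attrs:
            tw, ts = window_spec.samples(rec.fs)
            attrs = {
                "tw": tw,
                "ts": ts,
                "tw_ms": window_spec.tw_ms,
                "ts_ms": window_spec.ts_ms,
                "channels": rec.n_channels,
                "q": q,
                "gadf_formula": gadf_formula,
                "normalization": "per-image min-max to [0, 1]",
            }
    return _assemble(samples, class_map, len(class_map), attrs)


def build_dataset(
    recordings,
    window_spec: WindowSpec,
    split: SplitSpec = DEFAULT_DB1_SPLIT,
    q: int = 8,
    gadf_formula: str = "cos_diff",
) -> tuple[EncodedDataset, EncodedDataset]:
    """Window, encode, and split recordings into train/test image datasets.

    Every window of a repetition lands on exactly the split side its
    repetition index selects; a repetition in neither side is a
    configuration error.  The class mapping is shared by both sides.
    """
    full = encode_recordings(recordings, window_spec, q=q,
                             gadf_formula=gadf_formula)
    sides = np.array([split.side(int(r)) for r in full.repetitions])
    return (
        full.subset(np.flatnonzero(sides == "train")),
        full.subset(np.flatnonzero(sides == "test")),
    )
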