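"""File I/O: MAT recordings, arm-band CSV exports, HDF5 image datasets,
and network checkpoints."""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from . import nn
from .models import ModelSpec, build_network
from .windows import Recording

__all__ = [
    "SEGMENTED_NAME_RE",
    "parse_segmented_name",
    "load_recording_mat",
    "save_recording_mat",
    "load_armband_csv",
    "save_encoded_h5",
    "load_encoded_h5",
    "save_checkpoint",
    "load_checkpoint",
    "save_image_png",
]

# per-movement segmented files: subject_stimulus_repetition, 3-digit zero-padded
SEGMENTED_NAME_RE = re.compile(r"^(\d{3})_(\d{3})_(\d{3})\.mat$")


def parse_segmented_name(name: str) -> tuple[int, int, int] | None:
    """Parse `SSS_GGG_RRR.mat` into (subject, stimulus, repetition) or None."""
    m = SEGMENTED_NAME_RE.match(name)
    if m is None:
        return None
    return tuple(int(g) for g in m.groups())


def _scalar(value, default):
    if value is None:
        return default
    arr = np.asarray(value).ravel()
    if arr.size == 0:
        return default
    return int(arr[0])


def load_recording_mat(path: str | Path, fs: float = 100.0,
                       subject: int | None = None,
                       stimulus: int | None = None,
                       repetition: int | None = None) -> Recording:
    """Load a MAT v5 recording with an `emg` matrix (samples x channels).

    Scalar/vector keys `subject`, `stimulus`, `repetition` are honoured when
    present; explicit arguments (e.g. parsed from a segmented filename)
    override them.
    """
    path = Path(path)
    try:
        mat = loadmat(path)
    except Exception as exc:  # pragma: no cover - depends on corrupt input
        raise OSError(f"cannot read MAT file {path}: {exc}") from exc
    if "emg" not in mat:
        raise OSError(f"MAT file {path} has no 'emg' matrix")
    emg = np.asarray(mat["emg"], dtype=np.float64)
    parsed = parse_segmented_name(path.name)
    if parsed is not None:
        p_subject, p_stimulus, p_repetition = parsed
    else:
        p_subject = p_stimulus = p_repetition = None
    return Recording(
        signal=emg,
        fs=float(np.asarray(mat.get("fs", fs)).ravel()[0]) if "fs" in mat else fs,
        subject=subject if subject is not None
        else _scalar(mat.get("subject"), p_subject if p_subject is not None else 1),
        stimulus=stimulus if stimulus is not None
        else _scalar(mat.get("stimulus"), p_stimulus if p_stimulus is not None else 0),
        repetition=repetition if repetition is not None
        else _scalar(mat.get("repetition"), p_repetition if p_repetition is not None else 1),
    )


def save_recording_mat(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a MAT v5 file with emg/stimulus/repetition/subject keys."""
    path = Path(path)
    savemat(
        path,
        {
            "emg": rec.signal,
            "stimulus": np.array([[rec.stimulus]]),
            "repetition": np.array([[rec.repetition]]),
            "subject": np.array([[rec.subject]]),
            "fs": np.array([[rec.fs]]),
        },
    )
    return path


def load_armband_csv(path: str | Path, fs: float = 500.0,
                     subject: int = 1, stimulus: int = 0,
                     repetition: int = 1) -> Recording:
    """Load an 8-channel arm-band CSV export: one row per sample, one column
    per channel, optional header row."""
    path = Path(path)
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = not np.issubdtype(np.asarray(first.iloc[0]).dtype, np.number)
    df = pd.read_csv(path, header=0 if has_header else None)
    signal = df.to_numpy(dtype=np.float64)
    return Recording(signal=signal, fs=fs, subject=subject,
                     stimulus=stimulus, repetition=repetition)


def save_encoded_h5(dataset, path: str | Path) -> Path:
    """Write an encoded image dataset (see `semgimg.datasets.EncodedDataset`)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for stream, arr in dataset.images.items():
            f.create_dataset(stream, data=np.asarray(arr, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(dataset.labels, dtype=np.int64))
        f.create_dataset("subject", data=np.asarray(dataset.subjects, dtype=np.int64))
        f.create_dataset("repetition",
                         data=np.asarray(dataset.repetitions, dtype=np.int64))
        f.create_dataset("start_index",
                         data=np.asarray(dataset.start_indices, dtype=np.int64))
        for key, value in dataset.attrs.items():
            f.attrs[key] = value
        f.attrs["class_count"] = dataset.class_count
        f.attrs["class_map"] = json.dumps(dataset.class_map)
    return path


def load_encoded_h5(path: str | Path):
    from .datasets import EncodedDataset

    with h5py.File(path, "r") as f:
        images = {k: f[k][...] for k in ("sigimg", "gadf", "mtf") if k in f}
        labels = f["labels"][...]
        subjects = f["subject"][...]
        repetitions = f["repetition"][...]
        start_indices = f["start_index"][...]
        attrs = {k: f.attrs[k] for k in f.attrs if k not in ("class_count", "class_map")}
        class_count = int(f.attrs["class_count"])
        class_map = {int(k): v for k, v in json.loads(f.attrs["class_map"]).items()}
    return EncodedDataset(images=images, labels=labels, subjects=subjects,
                          repetitions=repetitions, start_indices=start_indices,
                          class_count=class_count, class_map=class_map,
                          attrs=attrs)


def save_checkpoint(net: nn.MultiStreamNet, spec: ModelSpec,
                    path: str | Path) -> Path:
    """Write weights + architecture JSON as a single .npz checkpoint."""
    path = Path(path)
    state = net.state_arrays()
    np.savez(path, __spec__=np.bytes_(spec.to_json().encode()), **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[nn.MultiStreamNet, ModelSpec]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec.from_json(bytes(data["__spec__"]).decode())
        net = build_network(spec, seed=0)
        net.load_state({k: data[k] for k in data.files if k != "__spec__"})
    return net, spec


def save_image_png(img: np.ndarray, path: str | Path, cmap: str = "viridis") -> Path:
    """Export one encoded image as a PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 2))
    ax.imshow(img, cmap=cmap, aspect="auto")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return path
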