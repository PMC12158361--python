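"""Training schedule, evaluation metrics, and the sklearn-style classifier.

Training follows the reference schedule: Adam on softmax cross-entropy,
batch size 100, 30 epochs, initial learning rate 0.1 divided by 10 at
epochs 16 and 24, dropout 0.5.  Evaluation reports per-subject accuracy
A_i = correct_i / total_i, their mean over subjects, macro-averaged
precision and recall, and the full confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import nn
from .datasets import EncodedDataset
from .models import ModelSpec, dscnn_spec, mscnn_spec, sscnn_spec, build_network
from .windows import ConfigurationError

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrainedModel",
    "learning_rate",
    "train",
    "evaluate",
    "compute_report",
    "cross_validate",
    "MultiStreamCNNClassifier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the reference settings."""

    batch_size: int = 100
    epochs: int = 30
    lr_initial: float = 0.1
    lr_drop_epochs: tuple[int, ...] = (16, 24)
    lr_drop_factor: float = 10.0
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be >= 1")
        if self.lr_initial <= 0 or self.lr_drop_factor <= 0:
            raise ConfigurationError("learning rates must be positive")
        if any(e < 1 for e in self.lr_drop_epochs):
            raise ConfigurationError("drop epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Learning rate at a 1-based epoch under the piecewise-constant decay."""
    drops = sum(1 for e in config.lr_drop_epochs if epoch >= e)
    return config.lr_initial / config.lr_drop_factor**drops


@dataclass
class TrainedModel:
    """A trained network bound to its architecture spec."""

    net: nn.MultiStreamNet
    spec: ModelSpec

    def predict_proba_arrays(self, xs: list[np.ndarray],
                             batch_size: int = 256) -> np.ndarray:
        n = xs[0].shape[0]
        out = np.empty((n, self.spec.class_count), dtype=np.float64)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            logits = self.net.forward([x[sl] for x in xs], training=False)
            out[sl] = nn.softmax(logits.astype(np.float64))
        return out

    def predict_proba(self, dataset: EncodedDataset,
                      batch_size: int = 256) -> np.ndarray:
        return self.predict_proba_arrays(dataset.streams(self.spec.streams),
                                         batch_size=batch_size)

    def predict(self, dataset: EncodedDataset, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(dataset, batch_size=batch_size).argmax(axis=1)


def _check_shapes(spec: ModelSpec, xs: list[np.ndarray]) -> None:
    for branch, x in zip(spec.branches, xs, strict=True):
        if tuple(x.shape[1:]) != tuple(branch.input_shape):
            raise ConfigurationError(
                f"{branch.stream} images of shape {x.shape[1:]} do not match "
                f"the branch input {branch.input_shape}"
            )


def _train_arrays(spec: ModelSpec, xs: list[np.ndarray], y: np.ndarray,
                  config: TrainConfig) -> tuple[TrainedModel, list[dict]]:
    _check_shapes(spec, xs)
    if y.size == 0:
        raise ConfigurationError("training set is empty")
    if y.max() >= spec.class_count:
        raise ConfigurationError("label outside the model's class range")
    net = build_network(spec, seed=config.seed)
    opt = nn.Adam(net, lr=config.lr_initial)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n = y.shape[0]
    history = []
    for epoch in range(1, config.epochs + 1):
        opt.lr = learning_rate(config, epoch)
        order = shuffle_rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [x[idx] for x in xs]
            yb = y[idx]
            logits = net.forward(batch, training=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step()
            losses.append(loss * idx.size)
            correct += int((probs.argmax(axis=1) == yb).sum())
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "loss": float(np.sum(losses) / n),
                "train_accuracy": correct / n,
            }
        )
        logger.info("epoch %d: lr=%.4g loss=%.4f acc=%.3f", epoch, opt.lr,
                    history[-1]["loss"], history[-1]["train_accuracy"])
    return TrainedModel(net=net, spec=spec), history


def train(model_spec: ModelSpec, train_dataset: EncodedDataset,
          config: TrainConfig = TrainConfig()) -> tuple[TrainedModel, list[dict]]:
    """Train a spec on an encoded dataset; returns the model and per-epoch history.

    Fully reproducible for a fixed seed and dataset order: initialization,
    shuffling, and dropout all derive from ``config.seed``.
    """
    xs = train_dataset.streams(model_spec.streams)
    return _train_arrays(model_spec, xs, train_dataset.labels, config)


@dataclass
class EvalReport:
    """Per-subject accuracies plus pooled precision/recall/confusion matrix."""

    per_subject_accuracy: dict[int, float]
    mean_accuracy: float
    precision: float
    recall: float
    confusion_matrix: np.ndarray
    overall_accuracy: float
    n_samples: int
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {
            "per_subject_accuracy": {str(k): v for k, v in
                                     self.per_subject_accuracy.items()},
            "mean_accuracy": self.mean_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "averaging": self.averaging,
            "n_samples": self.n_samples,
            "confusion_matrix": self.confusion_matrix.tolist(),
        }


def compute_report(y_true: np.ndarray, y_pred: np.ndarray,
                   subjects: np.ndarray, class_count: int,
                   averaging: str = "macro") -> EvalReport:
    """Build an evaluation report from labels, predictions, and subject ids.

    Per-subject accuracy is correct/total within each subject; the headline
    accuracy is the unweighted mean over subjects.  Precision and recall
    are per-class scores averaged with ``averaging`` ('macro' or 'micro').
    Subjects with no test windows are excluded (with a warning upstream).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    subjects = np.asarray(subjects)
    per_subject = {}
    for s in np.unique(subjects):
        mask = subjects == s
        per_subject[int(s)] = float((y_true[mask] == y_pred[mask]).mean())
    labels = np.arange(class_count)
    return EvalReport(
        per_subject_accuracy=per_subject,
        mean_accuracy=float(np.mean(list(per_subject.values()))),
        precision=float(precision_score(y_true, y_pred, labels=labels,
                                        average=averaging, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, labels=labels,
                                  average=averaging, zero_division=0)),
        confusion_matrix=_sk_confusion(y_true, y_pred, labels=labels),
        overall_accuracy=float((y_true == y_pred).mean()),
        n_samples=int(y_true.shape[0]),
        averaging=averaging,
    )


def evaluate(model: TrainedModel, test_dataset: EncodedDataset,
             averaging: str = "macro", batch_size: int = 256) -> EvalReport:
    """Evaluate a trained model on an encoded test dataset."""
    if len(test_dataset) == 0:
        raise ConfigurationError("test set is empty")
    y_pred = model.predict(test_dataset, batch_size=batch_size)
    return compute_report(test_dataset.labels, y_pred, test_dataset.subjects,
                          test_dataset.class_count, averaging=averaging)


def _default_trainer(config: TrainConfig, model_spec: ModelSpec):
    def trainer(train_subset: EncodedDataset) -> TrainedModel:
        model, _ = train(model_spec, train_subset, config)
        return model

    return trainer


def cross_validate(dataset: EncodedDataset, model_spec: ModelSpec | None = None,
                   config: TrainConfig = TrainConfig(), folds: int = 5,
                   repeats: int = 10, trainer=None) -> dict:
    """Repeated stratified k-fold cross-validation on one encoded dataset.

    Each repeat reshuffles the fold assignment with seed ``config.seed + r``
    and averages fold accuracies; the grand mean and standard deviation over
    repeats are returned.  Folds are stratified by class unless some class
    has fewer samples than ``folds``, in which case plain k-fold is used
    with a warning.  ``trainer`` may replace the CNN training closure with
    any callable mapping a training subset to an object with
    ``predict(dataset) -> labels``.
    """
    n = len(dataset)
    if n < folds:
        raise ConfigurationError("dataset smaller than the number of folds")
    if trainer is None:
        if model_spec is None:
            raise ConfigurationError("provide a model_spec or a trainer")
        trainer = _default_trainer(config, model_spec)
    _, class_counts = np.unique(dataset.labels, return_counts=True)
    stratified = bool(class_counts.min() >= folds)
    if not stratified:
        warnings.warn(
            "a class has fewer samples than folds; falling back to "
            "non-stratified k-fold",
            stacklevel=2,
        )
    per_repeat = []
    for r in range(repeats):
        seed_r = (config.seed + r) % 2**31
        cv = (StratifiedKFold if stratified else KFold)(
            n_splits=folds, shuffle=True, random_state=seed_r
        )
        fold_acc = []
        for train_idx, test_idx in cv.split(np.zeros(n), dataset.labels):
            model = trainer(dataset.subset(train_idx))
            test_subset = dataset.subset(test_idx)
            y_pred = model.predict(test_subset)
            fold_acc.append(float((y_pred == test_subset.labels).mean()))
        per_repeat.append(float(np.mean(fold_acc)))
    return {
        "mean_accuracy": float(np.mean(per_repeat)),
        "std_accuracy": float(np.std(per_repeat)),
        "per_repeat": per_repeat,
        "folds": folds,
        "repeats": repeats,
        "stratified": stratified,
    }


class MultiStreamCNNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style classifier over flattened (sigimg | gadf | mtf) features.

    Consumes the feature matrix produced by
    :class:`~semgimg.encoders.WindowImageEncoder` — each row is the
    concatenation of the three flattened images of one window — so it
    composes with sklearn pipelines and model selection.  The architecture
    (``arch`` in {'mscnn', 'dscnn', 'sscnn'} with its ``streams``) selects
    which image blocks feed the network.

    Parameters mirror the reference training schedule; ``width_scale``
    shrinks conv filter counts for desk-scale runs, and ``fc_sizes``
    overrides the fusion widths (None keeps each architecture's default).

    Attributes (after fit): ``classes_``, ``model_`` (the trained network),
    ``history_`` (per-epoch loss/accuracy), ``n_features_in_``.
    """

    def __init__(self, arch: str = "mscnn",
                 streams: tuple[str, ...] | None = None,
                 tw: int = 20, channels: int = 10, width_scale: float = 1.0,
                 fc_sizes: tuple[int, int] | None = None,
                 epochs: int = 30, batch_size: int = 100, lr: float = 0.1,
                 lr_drop_epochs: tuple[int, ...] = (16, 24),
                 lr_drop_factor: float = 10.0, dropout: float = 0.5,
                 batchnorm: bool = True, random_state: int = 0):
        self.arch = arch
        self.streams = streams
        self.tw = tw
        self.channels = channels
        self.width_scale = width_scale
        self.fc_sizes = fc_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_drop_epochs = lr_drop_epochs
        self.lr_drop_factor = lr_drop_factor
        self.dropout = dropout
        self.batchnorm = batchnorm
        self.random_state = random_state

    # feature layout produced by WindowImageEncoder
    def _feature_slices(self) -> dict[str, tuple[slice, tuple[int, int]]]:
        tw, C = self.tw, self.channels
        sizes = {"sigimg": (tw, C * C), "gadf": (tw, C * tw), "mtf": (tw, C * tw)}
        out = {}
        offset = 0
        for name in ("sigimg", "gadf", "mtf"):
            h, w = sizes[name]
            out[name] = (slice(offset, offset + h * w), (h, w))
            offset += h * w
        self._n_features = offset
        return out

    def _resolve_spec(self, n_classes: int) -> ModelSpec:
        streams = self.streams
        kw = dict(class_count=n_classes, tw=self.tw, channels=self.channels,
                  width_scale=self.width_scale)
        if self.arch == "mscnn":
            spec = mscnn_spec(**kw) if self.fc_sizes is None else \
                mscnn_spec(**kw, fc_sizes=tuple(self.fc_sizes))
        elif self.arch == "sscnn":
            if streams is None or len(streams) != 1:
                raise ConfigurationError("sscnn needs exactly one stream")
            spec = sscnn_spec(streams[0], fc_sizes=self.fc_sizes and
                              tuple(self.fc_sizes), **kw)
        elif self.arch == "dscnn":
            if streams is None or len(streams) != 2:
                raise ConfigurationError("dscnn needs exactly two streams")
            spec = dscnn_spec(tuple(streams), **kw) if self.fc_sizes is None else \
                dscnn_spec(tuple(streams), fc_sizes=tuple(self.fc_sizes), **kw)
        else:
            raise ConfigurationError(f"unknown architecture: {self.arch!r}")
        if not spec.batchnorm == self.batchnorm or spec.dropout_rate != self.dropout:
            spec = replace(spec, batchnorm=self.batchnorm,
                           dropout_rate=self.dropout)
        return spec

    def _split_features(self, X: np.ndarray,
                        streams: tuple[str, ...]) -> list[np.ndarray]:
        slices = self._feature_slices()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self._n_features:
            raise ValueError(
                f"X must have {self._n_features} features for tw={self.tw}, "
                f"channels={self.channels}; got shape {X.shape}"
            )
        out = []
        for name in streams:
            sl, (h, w) = slices[name]
            out.append(np.ascontiguousarray(X[:, sl]).reshape(-1, h, w, 1))
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.shape[0] < 2:
            raise ValueError("need at least 2 classes")
        spec = self._resolve_spec(len(self.classes_))
        xs = self._split_features(X, spec.streams)
        config = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                             lr_initial=self.lr,
                             lr_drop_epochs=tuple(self.lr_drop_epochs),
                             lr_drop_factor=self.lr_drop_factor,
                             dropout=self.dropout, seed=self.random_state)
        self.model_, self.history_ = _train_arrays(spec, xs, y_idx, config)
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        xs = self._split_features(np.asarray(X, dtype=np.float32),
                                  self.spec_.streams)
        return self.model_.predict_proba_arrays(xs)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
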