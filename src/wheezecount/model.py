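"""Segment classifier: 1-D CNN front end + bidirectional LSTM.

Each 128-value Mel vector is treated as a length-128 sequence with one
channel; two same-padded convolutions, max-pooling and dropout feed a
bidirectional LSTM whose final states pass through a ReLU dense layer into a
3-way softmax. The LSTM therefore runs across the Mel-frequency axis of a
single segment — temporal context across segments is handled downstream by
the counting layer.

The implementation is plain numpy (see :mod:`wheezecount._nn`); no GPU or
deep-learning framework is required.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import _nn
from .preprocess import FeatureMatrix

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SegmentClassifier",
    "build_model",
    "train",
    "cross_validate",
    "predict",
    "contiguous_folds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults follow the published description where stated (kernel 16,
    32 filters, two conv layers, 256 bidirectional LSTM units, 128 dense
    units, softmax over 3 classes); dropout rates are conventional choices
    as the source does not state them.
    """

    input_len: int = 128
    conv_blocks: int = 2
    filters: int = 32
    kernel: int = 16
    pool: int = 2
    dropout_conv: float = 0.25
    lstm_units: int = 256
    bidirectional: bool = True
    dense_units: int = 128
    dropout_dense: float = 0.5
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("this pipeline is defined for exactly 3 classes")
        if self.kernel > self.input_len:
            raise ValueError("kernel size cannot exceed input length")
        for name in ("input_len", "conv_blocks", "filters", "kernel", "pool",
                     "lstm_units", "dense_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_conv", "dropout_dense"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; data order is preserved (no shuffling)."""

    folds: int = 10
    shuffle: bool = False
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    #: None, "balanced" (inverse frequency) or an explicit {class: weight}
    #: mapping; off by default
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("invalid optimization settings")
        if not (
            self.class_weight is None
            or self.class_weight == "balanced"
            or isinstance(self.class_weight, dict)
        ):
            raise ValueError("class_weight must be None, 'balanced' or a dict")


class SegmentClassifier:
    """Trainable per-segment classifier with save/load support."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        c_in = 1
        for _ in range(config.conv_blocks):
            layers.append(_nn.Conv1D(c_in, config.filters, config.kernel, rng))
            c_in = config.filters
        layers.append(_nn.MaxPool1D(config.pool))
        layers.append(_nn.Dropout(config.dropout_conv))
        layers.append(_nn.BiLSTM(c_in, config.lstm_units, rng))
        lstm_out = 2 * config.lstm_units if config.bidirectional else config.lstm_units
        if not config.bidirectional:
            raise NotImplementedError("only the bidirectional variant is implemented")
        layers.append(_nn.Dense(lstm_out, config.dense_units, rng, relu=True))
        layers.append(_nn.Dropout(config.dropout_dense))
        layers.append(_nn.Dense(config.dense_units, config.n_classes, rng, relu=False))
        self.layers = layers

    # -- plumbing ---------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.size for lyr in self.layers for p in lyr.params.values())

    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        out = x
        for lyr in self.layers:
            out = lyr.forward(out, train, rng)
        return _nn.softmax(out)

    def _check_features(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        arr = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
        if arr.ndim != 2 or (arr.shape[0] > 0 and arr.shape[1] != self.config.input_len):
            raise ValueError(
                f"expected feature rows of length {self.config.input_len}, got shape {arr.shape}"
            )
        return arr.astype(_nn.F32)

    @staticmethod
    def _standardize(arr: np.ndarray) -> np.ndarray:
        """Input scaling applied before the network.

        Features arrive as dB rows (roughly [-80, 0]). Two components are
        combined on one channel: a spectrally whitened term (row minus its
        11-bin moving average) that exposes narrowband tonal structure to
        the convolutions, and a row-mean loudness offset that preserves the
        quiet-break / loud-breath contrast.
        """
        if arr.shape[0] == 0:
            return arr
        smooth = uniform_filter1d(arr, size=11, axis=1, mode="nearest")
        return (arr - smooth) / 10.0 + (arr.mean(axis=1, keepdims=True) + 40.0) / 40.0

    # -- training ---------------------------------------------------------
    def fit(
        self,
        features: FeatureMatrix | np.ndarray,
        labels: np.ndarray,
        cfg: TrainConfig = TrainConfig(),
    ) -> dict[str, list[float]]:
        """Train in-place; returns per-epoch history (loss, accuracy)."""
        x = self._standardize(self._check_features(features))
        y = np.asarray(labels, dtype=np.int64)
        if len(x) != len(y):
            raise ValueError("features and labels length mismatch")
        if not np.isin(y, [0, 1, 2]).all():
            raise ValueError("labels must be in {0, 1, 2}")
        history: dict[str, list] = {"loss": [], "accuracy": []}
        present = np.unique(y)
        missing = sorted(set(range(self.config.n_classes)) - set(present.tolist()))
        if missing:
            warnings.warn(f"classes absent from training labels: {missing}", stacklevel=2)
            history["missing_classes"] = missing
        if cfg.epochs == 0 or len(x) == 0:
            return history

        rng = np.random.default_rng(cfg.seed)
        optimizer = _nn.Adam(self.layers, lr=cfg.learning_rate)
        x3 = x[:, :, None]
        n = len(x)
        order = np.arange(n)
        sample_weight = None
        if cfg.class_weight == "balanced":
            counts = np.bincount(y, minlength=self.config.n_classes).astype(np.float64)
            weights = np.where(counts > 0, n / (self.config.n_classes * np.maximum(counts, 1)), 0.0)
            sample_weight = weights[y]
        elif isinstance(cfg.class_weight, dict):
            weights = np.array([
                float(cfg.class_weight.get(k, 1.0)) for k in range(self.config.n_classes)
            ])
            sample_weight = weights[y]
        for epoch in range(cfg.epochs):
            if cfg.shuffle:
                order = rng.permutation(n)
            total_loss = 0.0
            total_correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs = self._forward(x3[idx], train=True, rng=rng)
                loss, dlogits = _nn.cross_entropy_grad(
                    probs, y[idx],
                    None if sample_weight is None else sample_weight[idx],
                )
                grad = dlogits
                for lyr in reversed(self.layers):
                    grad = lyr.backward(grad)
                optimizer.step()
                total_loss += loss * len(idx)
                total_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            history["loss"].append(total_loss / n)
            history["accuracy"].append(total_correct / n)
            logger.info(
                "epoch %d/%d loss=%.4f acc=%.4f",
                epoch + 1, cfg.epochs, history["loss"][-1], history["accuracy"][-1],
            )
        return history

    # -- inference --------------------------------------------------------
    def predict_proba(self, features: FeatureMatrix | np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, shape (n_segments, 3); rows sum to 1."""
        x = self._standardize(self._check_features(features))
        if len(x) == 0:
            return np.zeros((0, self.config.n_classes))
        rng = np.random.default_rng(0)  # unused: dropout is off at inference
        out = [
            self._forward(x[i : i + batch_size][:, :, None], train=False, rng=rng)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out).astype(np.float64)

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        weights = {
            f"layer{i}:{key}": value
            for i, lyr in enumerate(self.layers)
            for key, value in lyr.params.items()
        }
        np.savez(directory / "weights.npz", **weights)
        with open(directory / "config.json", "w", encoding="utf-8") as fh:
            json.dump({"model": asdict(self.config), "seed": self.seed}, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "SegmentClassifier":
        directory = Path(directory)
        with open(directory / "config.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["model"]), seed=meta.get("seed", 0))
        with np.load(directory / "weights.npz") as data:
            for i, lyr in enumerate(model.layers):
                for key in lyr.params:
                    lyr.params[key][...] = data[f"layer{i}:{key}"]
        return model


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> SegmentClassifier:
    """Construct an untrained classifier (deterministic for a fixed seed)."""
    return SegmentClassifier(config, seed=seed)


def train(
    model: SegmentClassifier,
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[SegmentClassifier, dict[str, list[float]]]:
    """Train ``model`` in place and return it with the epoch history."""
    history = model.fit(features, labels, cfg)
    return model, history


def predict(model: SegmentClassifier, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-segment probability triples (p_break, p_normal, p_wheeze)."""
    return model.predict_proba(features)


def contiguous_folds(n: int, folds: int) -> list[np.ndarray]:
    """Split range(n) into ``folds`` contiguous, order-preserving blocks."""
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    return np.array_split(np.arange(n), folds)


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    mcfg: ModelConfig = ModelConfig(),
    tcfg: TrainConfig = TrainConfig(),
) -> tuple[list[float], SegmentClassifier]:
    """Unshuffled k-fold cross-validation.

    The sample order is preserved: folds are contiguous index blocks, every
    sample lands in the validation split exactly once. Returns per-fold
    validation accuracies and the highest-accuracy model.
    """
    arr = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=np.int64)
    folds = contiguous_folds(len(arr), tcfg.folds)
    accuracies: list[float] = []
    best_model: SegmentClassifier | None = None
    best_acc = -1.0
    for fold_idx, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(arr)), val_idx)
        model = build_model(mcfg, seed=tcfg.seed)
        model.fit(arr[train_idx], y[train_idx], replace(tcfg, seed=tcfg.seed + fold_idx))
        probs = model.predict_proba(arr[val_idx])
        acc = float(np.mean(probs.argmax(axis=1) == y[val_idx])) if len(val_idx) else 0.0
        accuracies.append(acc)
        logger.info("fold %d/%d validation accuracy %.4f", fold_idx + 1, tcfg.folds, acc)
        if acc > best_acc:
            best_acc = acc
            best_model = model
    assert best_model is not None
    return accuracies, best_model
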