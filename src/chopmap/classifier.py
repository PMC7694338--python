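"""Tile classifier: a small convolutional network with an sklearn API.

:class:`LeNetClassifier` follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it
composes with sklearn pipelines and model selection. Inputs are
``(n, s, s, 3)`` uint8 tile stacks; pixels are scaled to [0, 1] and no
mean image is subtracted. Training is plain SGD with momentum on the
softmax cross entropy, 30 epochs at learning rate 0.01 with train batches
of 64 and validation batches of 32 by default.

The corpus-level helpers :func:`train_classifier` and
:func:`predict_tiles` operate on :class:`~chopmap.tiling.LabeledTileCorpus`
and tile lists directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn.functional import cross_entropy, softmax
from .nn.network import LeNetNetwork, SGDMomentum, build_lenet
from .tiling import LabeledTileCorpus, Tile

__all__ = [
    "LeNetClassifier",
    "TrainHyperparams",
    "train_classifier",
    "predict_tiles",
    "save_classifier",
    "load_classifier",
]

CHECKPOINT_VERSION = 1
_PREDICT_CHUNK = 256


@dataclass(frozen=True)
class TrainHyperparams:
    """Training hyperparameters; defaults are the published settings."""

    epochs: int = 30
    learning_rate: float = 0.01
    train_batch_size: int = 64
    validation_batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.train_batch_size, self.validation_batch_size) < 1:
            raise ValueError("epochs and batch sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class LeNetClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional tile classifier (two conv + two pool + dense stack).

    Parameters
    ----------
    epochs, learning_rate, batch_size, val_batch_size, momentum
        SGD settings; defaults follow the published training protocol.
    pooling
        ``"max"`` (default) or ``"average"``.
    validation_fraction
        Used only when ``fit`` is called without an explicit validation
        set: that fraction of the data is held out (after shuffling).
    random_state
        Seeds weight initialisation, batch shuffling and the internal
        validation split; fits are bitwise reproducible given the seed.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in declared order (sorted; argmax ties resolve to the
        first).
    network_ : LeNetNetwork
        The fitted layer stack.
    history_ : pandas.DataFrame
        One row per epoch: ``epoch, train_loss, val_loss, val_accuracy``
        (losses are mean cross entropy per instance).
    """

    def __init__(
        self,
        epochs: int = 30,
        learning_rate: float = 0.01,
        batch_size: int = 64,
        val_batch_size: int = 32,
        momentum: float = 0.9,
        pooling: str = "max",
        validation_fraction: float = 0.25,
        random_state: int | None = None,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.val_batch_size = val_batch_size
        self.momentum = momentum
        self.pooling = pooling
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._check_tiles(np.asarray(X))
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            order = rng.permutation(X.shape[0])
            n_train = X.shape[0] - int(np.floor(self.validation_fraction * X.shape[0]))
            X, X_val = X[order[:n_train]], X[order[n_train:]]
            y, y_val = y[order[:n_train]], y[order[n_train:]]
        else:
            X_val = self._check_tiles(np.asarray(X_val))
            y_val = np.asarray(y_val, dtype=object)

        self.classes_ = np.unique(np.concatenate([y, y_val]))
        if len(self.classes_) < 2:
            raise ValueError(
                f"training data contains a single class {self.classes_[0]!r}; "
                "need both classes"
            )
        class_index = {c: i for i, c in enumerate(self.classes_)}
        t_train = _one_hot(y, class_index)
        t_val = _one_hot(y_val, class_index)

        self.input_size_ = int(X.shape[1])
        spec = build_lenet(
            self.input_size_, in_channels=3, n_classes=len(self.classes_), pooling=self.pooling
        )
        self.network_ = LeNetNetwork(spec, rng)
        opt = SGDMomentum(self.network_, self.learning_rate, self.momentum)

        Xs = self._scale(X)
        Xv = self._scale(X_val)
        records = []
        n = Xs.shape[0]
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            loss_sum, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs = softmax(self.network_.forward(Xs[idx]), axis=1)
                batch_loss = cross_entropy(probs, t_train[idx], reduction="sum")
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                loss_sum += batch_loss
                seen += len(idx)
                self.network_.backward_from_probs(probs, t_train[idx])
                opt.step()
            val_loss, val_acc = self._evaluate(Xv, t_val)
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            records.append(
                {
                    "epoch": epoch,
                    "train_loss": loss_sum / seen,
                    "val_loss": val_loss,
                    "val_accuracy": val_acc,
                }
            )
        self.history_ = pd.DataFrame.from_records(records)
        return self

    def _evaluate(self, Xv: np.ndarray, t_val: np.ndarray) -> tuple[float, float]:
        loss_sum, correct = 0.0, 0
        for start in range(0, Xv.shape[0], self.val_batch_size):
            sl = slice(start, start + self.val_batch_size)
            probs = softmax(self.network_.forward(Xv[sl]), axis=1)
            loss_sum += cross_entropy(probs, t_val[sl], reduction="sum")
            correct += int(np.sum(np.argmax(probs, 1) == np.argmax(t_val[sl], 1)))
        n = Xv.shape[0]
        return loss_sum / n, correct / n

    # -------------------------------------------------------------- predict
    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._check_tiles(np.asarray(X), expected=self.input_size_)
        out = np.empty((X.shape[0], len(self.classes_)))
        Xs = self._scale(X)
        for start in range(0, X.shape[0], _PREDICT_CHUNK):
            sl = slice(start, start + _PREDICT_CHUNK)
            out[sl] = softmax(self.network_.forward(Xs[sl]), axis=1)
        return out

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]  # argmax ties -> first class

    # -------------------------------------------------------------- helpers
    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")

    @staticmethod
    def _scale(X: np.ndarray) -> np.ndarray:
        return (X.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)

    @staticmethod
    def _check_tiles(X: np.ndarray, expected: int | None = None) -> np.ndarray:
        if X.ndim != 4 or X.shape[3] != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"expected (n, s, s, 3) tile stack, got shape {X.shape}")
        if expected is not None and X.shape[1] != expected:
            raise ValueError(
                f"tile size mismatch: model expects {expected}, got {X.shape[1]}"
            )
        return X


def _one_hot(y: np.ndarray, class_index: dict) -> np.ndarray:
    t = np.zeros((len(y), len(class_index)))
    for i, label in enumerate(y):
        t[i, class_index[label]] = 1.0
    return t


# -------------------------------------------------------- corpus-level API


def train_classifier(corpus: LabeledTileCorpus, hp: TrainHyperparams) -> LeNetClassifier:
    """Train on a corpus using its stored train/validation split."""
    X_train, y_train = corpus.pixel_array("train")
    X_val, y_val = corpus.pixel_array("validation")
    for name, labels in (("train", y_train), ("validation", y_val)):
        if len(np.unique(labels)) < 2:
            raise ValueError(f"{name} split does not contain both classes")
    clf = LeNetClassifier(
        epochs=hp.epochs,
        learning_rate=hp.learning_rate,
        batch_size=hp.train_batch_size,
        val_batch_size=hp.validation_batch_size,
        momentum=hp.momentum,
        random_state=hp.seed,
    )
    return clf.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def predict_tiles(
    model: LeNetClassifier, tiles: Sequence[Tile]
) -> list[tuple[str, np.ndarray]]:
    """Per-tile (label, probability vector) for a list of tiles."""
    if not tiles:
        return []
    X = np.stack([t.pixels for t in tiles])
    probs = model.predict_proba(X)
    labels = model.classes_[np.argmax(probs, axis=1)]
    return [(str(l), p) for l, p in zip(labels, probs)]


# ---------------------------------------------------------- serialization


def save_classifier(model: LeNetClassifier, path: str | Path) -> Path:
    """Write a single-file checkpoint (architecture + weights + classes).

    Reloading yields bit-identical predictions.
    """
    model._check_fitted()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "input_size": model.input_size_,
        "pooling": model.pooling,
        "classes": [str(c) for c in model.classes_],
        "preprocessing": "scale_0_1",
        "params": model.get_params(),
    }
    arrays = {}
    for i, layer in enumerate(model.network_.param_layers):
        arrays[f"W_{i}"] = layer.params[0]
        arrays[f"b_{i}"] = layer.params[1]
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_classifier(path: str | Path) -> LeNetClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = LeNetClassifier(**meta["params"])
        model.classes_ = np.asarray(meta["classes"], dtype=object)
        model.input_size_ = int(meta["input_size"])
        spec = build_lenet(
            model.input_size_,
            in_channels=3,
            n_classes=len(model.classes_),
            pooling=meta["pooling"],
        )
        model.network_ = LeNetNetwork(spec, np.random.default_rng(0))
        for i, layer in enumerate(model.network_.param_layers):
            layer.params[0][...] = data[f"W_{i}"]
            layer.params[1][...] = data[f"b_{i}"]
        model.history_ = pd.DataFrame()
    return model
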