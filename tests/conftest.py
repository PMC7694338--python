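"""Shared fixtures: synthetic corpora, trained models, stub classifiers."""

from __future__ import annotations

import numpy as np
import pytest

from chopmap.classifier import TrainHyperparams, train_classifier
from chopmap.experiments import build_easy_corpus
from chopmap.synthetic import CLASS_PRESETS, generate_class_image

EASY_SEED = 1234


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def easy_corpus():
    """Well-separated 2-class corpus: 500 tiles/class, 28-px tiles."""
    return build_easy_corpus(n_per_class=500, tile_size=28, seed=EASY_SEED)


@pytest.fixture(scope="session")
def easy_model(easy_corpus):
    """Classifier trained on the easy corpus with the default protocol
    (30 epochs, lr 0.01, batch 64)."""
    return train_classifier(easy_corpus, TrainHyperparams(epochs=30, seed=EASY_SEED))


@pytest.fixture(scope="session")
def tiny_corpus_14():
    """Small 14-px corpus for fast training-behaviour tests."""
    return build_easy_corpus(n_per_class=120, tile_size=14, seed=7, dims=64)


def make_class_image(class_name: str, seed: int, dims: int = 64):
    return generate_class_image(CLASS_PRESETS[class_name], dims, dims, seed)


class StubClassifier:
    """Fixed-rule tile classifier exposing the estimator surface that
    scene mapping and evaluation need (predict, classes_, input_size_)."""

    def __init__(self, input_size: int, rule=None, constant: str | None = None):
        self.input_size_ = input_size
        self.classes_ = np.asarray(["bamboo", "other"], dtype=object)
        self._rule = rule
        self._constant = constant

    def predict(self, X):
        X = np.asarray(X)
        if self._constant is not None:
            return np.asarray([self._constant] * X.shape[0], dtype=object)
        return np.asarray([self._rule(t) for t in X], dtype=object)
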