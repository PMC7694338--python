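"""GLCM-texture SVM baseline: the conventional classifier compared against.

Each tile is summarised by an 8-dimensional feature vector: the three
per-channel RGB means plus five grey-level co-occurrence texture measures
(mean, variance, contrast, homogeneity, dissimilarity) computed on the
luminance image. Classification uses an RBF-kernel support vector machine
whose gamma and cost are chosen by cross-validated grid search.

Defaults (the original protocol leaves them open): ITU-R BT.601 luminance
weights, 32 grey levels, the four distance-1 offsets (1,0), (0,1), (1,1),
(1,-1) with counts summed across offsets and symmetrised before
normalising, z-score feature standardisation, and powers-of-two grids
gamma in 2^-8..2^2, cost in 2^-2..2^6 with 5-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GLCMConfig",
    "to_luminance",
    "quantize",
    "compute_glcm",
    "glcm_measures",
    "extract_feature_vector",
    "extract_features",
    "train_svm_baseline",
    "TextureSVM",
]

BT601_WEIGHTS = (0.299, 0.587, 0.114)
DEFAULT_OFFSETS = ((1, 0), (0, 1), (1, 1), (1, -1))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-8, 3))
DEFAULT_COST_GRID = tuple(2.0 ** np.arange(-2, 7))

FEATURE_NAMES = (
    "mean_r",
    "mean_g",
    "mean_b",
    "glcm_mean",
    "glcm_variance",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_dissimilarity",
)


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    luminance_weights: tuple[float, float, float] = BT601_WEIGHTS


def to_luminance(pixels: np.ndarray, weights: Sequence[float] = BT601_WEIGHTS) -> np.ndarray:
    """Weighted RGB -> luminance, value = wR*R + wG*G + wB*B per pixel."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("luminance weights must be positive and sum to 1")
    return np.asarray(pixels, dtype=float) @ w


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin [0, 255] luminance into integer levels 0..levels-1."""
    if levels < 2:
        raise ValueError("need at least 2 grey levels")
    q = np.floor(np.asarray(gray, dtype=float) * levels / 256.0).astype(np.int64)
    return np.minimum(q, levels - 1)


def compute_glcm(
    quantized: np.ndarray,
    levels: int,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Grey-level co-occurrence matrix over one or more pixel offsets.

    Counts ordered level pairs (value at p, value at p + (dx, dy)) over all
    in-bounds positions p, summed across the given offsets. ``symmetric``
    adds the transpose; ``normalize`` divides by the total count so the
    matrix sums to 1.
    """
    q = np.asarray(quantized)
    if q.ndim != 2:
        raise ValueError("quantized tile must be 2-D")
    h, w = q.shape
    P = np.zeros((levels, levels), dtype=float)
    for dx, dy in offsets:
        if dx == 0 and dy == 0:
            raise ValueError("offset (0, 0) is not allowed")
        if abs(dx) >= w or abs(dy) >= h:
            raise ValueError(f"tile {h}x{w} too small for offset ({dx}, {dy})")
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        ys2 = slice(max(0, dy), h - max(0, -dy))
        xs2 = slice(max(0, dx), w - max(0, -dx))
        a = q[ys, xs].ravel()
        b = q[ys2, xs2].ravel()
        np.add.at(P, (a, b), 1.0)
    if symmetric:
        P = P + P.T
    if normalize:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


def glcm_measures(P: np.ndarray) -> dict[str, float]:
    """The five texture measures of a normalised co-occurrence matrix.

    With mu = sum_ij i P(i,j): mean = mu; variance = sum (i-mu)^2 P;
    contrast = sum (i-j)^2 P; homogeneity = sum P / (1 + (i-j)^2);
    dissimilarity = sum |i-j| P.
    """
    P = np.asarray(P, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM must be normalised (sum to 1)")
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    mu = float(np.sum(i * P))
    return {
        "mean": mu,
        "variance": float(np.sum((i - mu) ** 2 * P)),
        "contrast": float(np.sum((i - j) ** 2 * P)),
        "homogeneity": float(np.sum(P / (1.0 + (i - j) ** 2))),
        "dissimilarity": float(np.sum(np.abs(i - j) * P)),
    }


def extract_feature_vector(pixels: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """8-vector: RGB channel means + the five GLCM texture measures."""
    px = np.asarray(pixels)
    rgb_means = px.reshape(-1, 3).mean(axis=0)
    gray = to_luminance(px, config.luminance_weights)
    q = quantize(gray, config.levels)
    P = compute_glcm(q, config.levels, config.offsets, symmetric=config.symmetric)
    m = glcm_measures(P)
    return np.array(
        [
            rgb_means[0],
            rgb_means[1],
            rgb_means[2],
            m["mean"],
            m["variance"],
            m["contrast"],
            m["homogeneity"],
            m["dissimilarity"],
        ]
    )


def extract_features(tiles: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Feature matrix (n, 8) for a stack of tiles."""
    return np.stack([extract_feature_vector(t, config) for t in tiles])


def train_svm_baseline(
    features: np.ndarray,
    labels: Sequence,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    folds: int = 5,
    seed: int | None = 0,
):
    """Grid-search an RBF SVM on precomputed feature vectors.

    Standardises features, evaluates every (cost, gamma) pair by stratified
    cross validation and keeps the pair with the highest mean accuracy
    (ties resolve to the smallest cost, then the smallest gamma), then
    refits on all data. Returns ``(pipeline, best)`` where ``best`` is a
    dict with ``gamma``, ``cost`` and ``cv_accuracy``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train the SVM baseline")
    if len(gamma_grid) == 0 or len(cost_grid) == 0:
        raise ValueError("parameter grids must be non-empty")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    best = None
    for cost in sorted(cost_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for tr, te in splits:
                pipe = _make_pipeline(gamma, cost)
                pipe.fit(X[tr], y[tr])
                accs.append(float(np.mean(pipe.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
            if best is None or score > best["cv_accuracy"]:
                best = {"gamma": float(gamma), "cost": float(cost), "cv_accuracy": score}
    final = _make_pipeline(best["gamma"], best["cost"])
    final.fit(X, y)
    return final, best


def _make_pipeline(gamma: float, cost: float) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", gamma=gamma, C=cost))]
    )


class TextureSVM(ClassifierMixin, BaseEstimator):
    """RBF-SVM tile classifier on RGB + GLCM texture features.

    sklearn-style estimator: ``fit`` takes an ``(n, s, s, 3)`` tile stack
    and labels, extracts the 8-dimensional feature vectors, grid-searches
    gamma and cost by stratified CV, and refits on all data.

    Attributes
    ----------
    classes_ : ndarray of class labels
    gamma_, cost_ : selected kernel parameters (members of the grids)
    cv_accuracy_ : mean CV accuracy of the selected grid point
    pipeline_ : fitted StandardScaler + SVC pipeline
    """

    def __init__(
        self,
        levels: int = 32,
        gamma_grid: tuple = DEFAULT_GAMMA_GRID,
        cost_grid: tuple = DEFAULT_COST_GRID,
        cv_folds: int = 5,
        random_state: int | None = 0,
    ):
        self.levels = levels
        self.gamma_grid = gamma_grid
        self.cost_grid = cost_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        config = GLCMConfig(levels=self.levels)
        feats = extract_features(np.asarray(X), config)
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        self.pipeline_, best = train_svm_baseline(
            feats,
            y,
            gamma_grid=self.gamma_grid,
            cost_grid=self.cost_grid,
            folds=self.cv_folds,
            seed=self.random_state,
        )
        self.gamma_ = best["gamma"]
        self.cost_ = best["cost"]
        self.cv_accuracy_ = best["cv_accuracy"]
        self._config = config
        return self

    def predict(self, X):
        feats = extract_features(np.asarray(X), self._config)
        return self.pipeline_.predict(feats)
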