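"""Desk-scale experiment orchestration over synthetic (or supplied) imagery.

Five experiment kinds mirror the original study designs:

* ``resolution`` — one model per (downsample factor, matched tile size),
  each evaluated at its own factor;
* ``grid_size`` — one model per chopping tile size at full resolution;
* ``robustness`` — models trained on decreasing numbers of tiles against
  a shared evaluation pool;
* ``transferability`` — per-site models plus a pooled "all" model, fully
  crossed over the test sites;
* ``svm_comparison`` — the convolutional classifier and the GLCM-texture
  SVM trained on identical corpora and evaluated on an identical pool.

Evaluation follows the no-overlap protocol: class-pure evaluation images
are chopped without overlap, tiles are pooled, a fixed number (500 by
default) is sampled with a seed, and the confusion matrix with accuracy,
recall and precision for both classes is reported. Evaluation images are
generated from seeds disjoint from the training seeds — the synthetic
stand-in for spatially separated sampling locations.

Full-scale defaults (e.g. 15000-tile corpora) are scalable through the
config so continuous-integration runs finish quickly; every report row
records the realised sizes, seeds and a config hash for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .baseline import TextureSVM
from .classifier import LeNetClassifier, TrainHyperparams, train_classifier
from .metrics import classification_metrics, confusion
from .raster import RasterImage
from .synthetic import SITE_STYLES, downsample_scene, generate_site
from .tiling import ChopSpec, LabeledTileCorpus, build_training_corpus, chop_image

__all__ = [
    "ExperimentConfig",
    "evaluate_model",
    "run_experiment",
    "subsample_corpus",
    "build_easy_corpus",
]

POSITIVE_CLASS = "bamboo"
_EVAL_SEED_OFFSET = 500_000  # keeps evaluation imagery seed-disjoint from training


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration for one experiment run.

    Defaults mirror the original designs: tile sizes {84, 56, 28} for the
    grid-size sweep, factor/tile pairs {(1,56), (2,28), (4,14)} for the
    resolution sweep, training-set sizes {15000, 1000, 100} for
    robustness, and 500 evaluation tiles. ``n_train_images_per_class``,
    ``image_dims`` and ``epochs`` set the scale of the synthetic corpus.
    """

    kind: str
    tile_sizes: tuple[int, ...] = (84, 56, 28)
    factor_tile_pairs: tuple[tuple[int, int], ...] = ((1, 56), (2, 28), (4, 14))
    train_sizes: tuple[int, ...] = (15000, 1000, 100)
    sites: tuple[str, ...] = ("site_a", "site_b", "site_c")
    tile_size: int = 56
    n_eval_tiles: int = 500
    seeds: tuple[int, ...] = (0,)
    n_train_images_per_class: int = 6
    n_eval_images_per_class: int = 4
    image_dims: int = 256
    epochs: int = 30

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ----------------------------------------------------------------- building


def _site_images(
    site: str, n_per_class: int, dims: int, seed: int
) -> list[tuple[RasterImage, str]]:
    style = SITE_STYLES.get(site, SITE_STYLES["site_a"])
    images, _ = generate_site(site, style, n_per_class, dims, seed)
    return images


def _downsampled(images, factor):
    return [(downsample_scene(img, factor), label) for img, label in images]


def subsample_corpus(corpus: LabeledTileCorpus, n: int, seed: int) -> LabeledTileCorpus:
    """Randomly keep n tiles of a corpus, re-splitting 75/25."""
    n = min(n, len(corpus))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(corpus))[:n]
    n_train = int(np.floor(0.75 * n))
    split = np.empty(n, dtype=object)
    split[:n_train] = "train"
    split[n_train:] = "validation"
    return LabeledTileCorpus(
        tiles=[corpus.tiles[i] for i in idx],
        labels=corpus.labels[idx],
        split=split,
        split_seed=seed,
        class_counts={
            c: int(np.sum(corpus.labels[idx] == c)) for c in np.unique(corpus.labels[idx])
        },
    )


def build_easy_corpus(
    n_per_class: int = 500,
    tile_size: int = 28,
    seed: int = 0,
    dims: int = 256,
) -> LabeledTileCorpus:
    """A well-separated two-class benchmark corpus (bamboo vs canopy).

    Generates enough class-pure synthetic images to yield at least
    ``n_per_class`` half-overlapping tiles per class, then keeps a random
    balanced subset of exactly ``n_per_class`` tiles per class with a
    stratified 75/25 split.
    """
    spec = ChopSpec(tile_size=tile_size, overlap_fraction=0.5)
    per_image = ((dims - tile_size) // spec.stride + 1) ** 2
    n_images = -(-n_per_class // per_image)
    images = _site_images("easy", n_images, dims, seed)
    corpus = build_training_corpus(images, spec, split_seed=seed)

    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in sorted(corpus.class_counts):
        idx = np.flatnonzero(corpus.labels == cls)
        keep.extend(idx[rng.permutation(len(idx))[:n_per_class]])
    keep = sorted(keep)
    n_train_per_class = int(np.floor(0.75 * n_per_class))
    labels = corpus.labels[keep]
    split = np.empty(len(keep), dtype=object)
    for cls in sorted(corpus.class_counts):
        idx = np.flatnonzero(labels == cls)
        order = rng.permutation(len(idx))
        split[idx[order[:n_train_per_class]]] = "train"
        split[idx[order[n_train_per_class:]]] = "validation"
    return LabeledTileCorpus(
        tiles=[corpus.tiles[i] for i in keep],
        labels=labels,
        split=split,
        split_seed=seed,
        class_counts={c: n_per_class for c in sorted(corpus.class_counts)},
    )


def _train_cnn(
    images, tile_size: int, seed: int, epochs: int, max_tiles: int | None = None
) -> tuple[LeNetClassifier, LabeledTileCorpus]:
    corpus = build_training_corpus(
        images, ChopSpec(tile_size=tile_size, overlap_fraction=0.5), split_seed=seed
    )
    if max_tiles is not None and max_tiles < len(corpus):
        corpus = subsample_corpus(corpus, max_tiles, seed)
    hp = TrainHyperparams(epochs=epochs, seed=seed)
    return train_classifier(corpus, hp), corpus


# --------------------------------------------------------------- evaluation


def evaluate_model(
    model,
    eval_images: list[tuple[RasterImage, str]],
    tile_size: int,
    n_eval_tiles: int = 500,
    seed: int = 0,
) -> dict:
    """No-overlap evaluation: pool tiles, sample, predict, score.

    ``eval_images`` are class-pure labeled rasters disjoint from the
    training sources. Returns a flat dict with the confusion-matrix counts
    (bamboo positive), accuracy, recall/precision for both classes, the
    realised class ratio, and any sampling shortfall.
    """
    spec = ChopSpec(tile_size=tile_size, overlap_fraction=0.0)
    pool: list[np.ndarray] = []
    truths: list[str] = []
    for image, label in eval_images:
        for tile in chop_image(image, spec):
            pool.append(tile.pixels)
            truths.append(label)
    if not pool:
        raise ValueError("evaluation images yielded no tiles")
    rng = np.random.default_rng(seed)
    n = min(n_eval_tiles, len(pool))
    idx = rng.permutation(len(pool))[:n]
    X = np.stack([pool[i] for i in idx])
    truth = np.asarray([truths[i] for i in idx], dtype=object)
    pred = np.asarray(model.predict(X), dtype=object)

    positive = POSITIVE_CLASS if POSITIVE_CLASS in set(truths) else sorted(set(truths))[0]
    cm = confusion(pred, truth, positive)
    pos_rates = classification_metrics(cm)
    neg_rates = classification_metrics(cm.complement())
    return {
        "n_eval": n,
        "shortfall": max(0, n_eval_tiles - len(pool)),
        "positive_class": positive,
        "positive_fraction": float(np.mean(truth == positive)),
        "tp": cm.tp,
        "fp": cm.fp,
        "fn": cm.fn,
        "tn": cm.tn,
        "accuracy": pos_rates.accuracy,
        "recall_bamboo": pos_rates.recall,
        "precision_bamboo": pos_rates.precision,
        "recall_other": neg_rates.recall,
        "precision_other": neg_rates.precision,
        "eval_seed": seed,
    }


# -------------------------------------------------------------- experiments


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run one experiment kind, returning one report row per condition."""
    runners = {
        "resolution": _run_resolution,
        "grid_size": _run_grid_size,
        "robustness": _run_robustness,
        "transferability": _run_transferability,
        "svm_comparison": _run_svm_comparison,
    }
    if config.kind not in runners:
        raise ValueError(f"unknown experiment kind {config.kind!r}")
    rows = runners[config.kind](config)
    df = pd.DataFrame(rows)
    df["kind"] = config.kind
    df["config_hash"] = config.config_hash()
    return df


def _train_eval_images(config: ExperimentConfig, site: str, seed: int):
    train = _site_images(
        site, config.n_train_images_per_class, config.image_dims, seed
    )
    eval_ = _site_images(
        site,
        config.n_eval_images_per_class,
        config.image_dims,
        seed + _EVAL_SEED_OFFSET,
    )
    return train, eval_


def _run_resolution(config: ExperimentConfig) -> list[dict]:
    rows = []
    site = config.sites[0]
    for seed in config.seeds:
        train_imgs, eval_imgs = _train_eval_images(config, site, seed)
        for factor, tile_size in config.factor_tile_pairs:
            model, corpus = _train_cnn(
                _downsampled(train_imgs, factor), tile_size, seed, config.epochs
            )
            report = evaluate_model(
                model,
                _downsampled(eval_imgs, factor),
                tile_size,
                config.n_eval_tiles,
                seed,
            )
            rows.append(
                {
                    "site": site,
                    "factor": factor,
                    "tile_size": tile_size,
                    "n_train_tiles": len(corpus),
                    "seed": seed,
                    **report,
                }
            )
    return rows


def _run_grid_size(config: ExperimentConfig) -> list[dict]:
    rows = []
    site = config.sites[0]
    for seed in config.seeds:
        train_imgs, eval_imgs = _train_eval_images(config, site, seed)
        for tile_size in config.tile_sizes:
            model, corpus = _train_cnn(train_imgs, tile_size, seed, config.epochs)
            report = evaluate_model(
                model, eval_imgs, tile_size, config.n_eval_tiles, seed
            )
            rows.append(
                {
                    "site": site,
                    "tile_size": tile_size,
                    "n_train_tiles": len(corpus),
                    "seed": seed,
                    **report,
                }
            )
    return rows


def _run_robustness(config: ExperimentConfig) -> list[dict]:
    rows = []
    site = config.sites[0]
    for seed in config.seeds:
        train_imgs, eval_imgs = _train_eval_images(config, site, seed)
        for size in config.train_sizes:
            model, corpus = _train_cnn(
                train_imgs, config.tile_size, seed, config.epochs, max_tiles=size
            )
            report = evaluate_model(
                model, eval_imgs, config.tile_size, config.n_eval_tiles, seed
            )
            rows.append(
                {
                    "site": site,
                    "train_size": size,
                    "n_train_tiles": len(corpus),
                    "tile_size": config.tile_size,
                    "seed": seed,
                    **report,
                }
            )
    return rows


def _run_transferability(config: ExperimentConfig) -> list[dict]:
    rows = []
    for seed in config.seeds:
        per_site = {
            site: _train_eval_images(config, site, seed) for site in config.sites
        }
        models = {}
        for site in config.sites:
            models[site], _ = _train_cnn(
                per_site[site][0], config.tile_size, seed, config.epochs
            )
        pooled = [img for site in config.sites for img in per_site[site][0]]
        models["all"], _ = _train_cnn(pooled, config.tile_size, seed, config.epochs)
        for train_site, model in models.items():
            for test_site in config.sites:
                report = evaluate_model(
                    model,
                    per_site[test_site][1],
                    config.tile_size,
                    config.n_eval_tiles,
                    seed,
                )
                rows.append(
                    {
                        "train_site": train_site,
                        "test_site": test_site,
                        "tile_size": config.tile_size,
                        "seed": seed,
                        **report,
                    }
                )
    return rows


def _run_svm_comparison(config: ExperimentConfig) -> list[dict]:
    rows = []
    site = config.sites[0]
    for seed in config.seeds:
        train_imgs, eval_imgs = _train_eval_images(config, site, seed)
        cnn, corpus = _train_cnn(train_imgs, config.tile_size, seed, config.epochs)
        X_train, y_train = corpus.pixel_array("train")
        svm = TextureSVM(random_state=seed).fit(X_train, y_train)
        for name, model in (("cnn", cnn), ("svm", svm)):
            report = evaluate_model(
                model, eval_imgs, config.tile_size, config.n_eval_tiles, seed
            )
            rows.append(
                {
                    "site": site,
                    "model": name,
                    "tile_size": config.tile_size,
                    "n_train_tiles": len(corpus),
                    "seed": seed,
                    **report,
                }
            )
    return rows
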