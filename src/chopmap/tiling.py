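"""The chopped-picture method: dissecting rasters into square tiles.

Class-pure source images are cut into small fixed-size squares on a regular
grid. For training-data generation adjacent tiles overlap by 50% both
vertically and horizontally; for evaluation and map inference the grid has
no overlap. Tiles inherit the class label of their parent image, are
shuffled, and split 75/25 into training and validation sets.

Partial tiles at the right/bottom edges are dropped, never padded, so every
tile has identical statistics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .raster import RasterImage

__all__ = [
    "ChopSpec",
    "Tile",
    "LabeledTileCorpus",
    "tile_count",
    "chop_image",
    "build_training_corpus",
    "write_corpus",
]

TRAIN_FRACTION = 0.75


@dataclass(frozen=True)
class ChopSpec:
    """Tile size and overlap for a chopping grid.

    ``overlap_fraction=0.5`` is the training regime; ``0`` the evaluation
    regime. The grid stride is ``round(tile_size * (1 - overlap_fraction))``
    with a floor of one pixel.
    """

    tile_size: int
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ValueError("tile_size must be a positive integer")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def stride(self) -> int:
        return max(1, round(self.tile_size * (1.0 - self.overlap_fraction)))


@dataclass
class Tile:
    """A square block of pixels with provenance in its parent raster."""

    pixels: np.ndarray
    parent: str
    row_index: int
    col_index: int
    origin: tuple[int, int]  # (x, y) of the top-left corner, 0-based

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class LabeledTileCorpus:
    """Shuffled, class-labeled tiles with a 75/25 train/validation split."""

    tiles: list[Tile]
    labels: np.ndarray  # per-tile class name
    split: np.ndarray  # per-tile "train" | "validation"
    split_seed: int
    class_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tiles)

    def subset(self, which: str) -> tuple[list[Tile], np.ndarray]:
        mask = self.split == which
        idx = np.flatnonzero(mask)
        return [self.tiles[i] for i in idx], self.labels[idx]

    def pixel_array(self, which: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack tile pixels into ``(n, s, s, 3)`` with matching labels."""
        if which is None:
            tiles, labels = self.tiles, self.labels
        else:
            tiles, labels = self.subset(which)
        return np.stack([t.pixels for t in tiles]), np.asarray(labels)


def tile_count(length: int, spec: ChopSpec) -> int:
    """Number of full tiles along an axis of the given pixel length.

    Trailing pixels that do not fill a tile are dropped.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if length < spec.tile_size:
        return 0
    return (length - spec.tile_size) // spec.stride + 1


def chop_image(image: RasterImage, spec: ChopSpec) -> list[Tile]:
    """Chop a raster into square tiles in row-major grid order.

    Every tile's pixels are an exact copy of the corresponding window; an
    image smaller than the tile size in either dimension yields an empty
    list.
    """
    n_cols = tile_count(image.width, spec)
    n_rows = tile_count(image.height, spec)
    s, stride = spec.tile_size, spec.stride
    tiles: list[Tile] = []
    for r in range(n_rows):
        y = r * stride
        for c in range(n_cols):
            x = c * stride
            tiles.append(
                Tile(
                    pixels=image.pixels[y : y + s, x : x + s].copy(),
                    parent=image.source_id,
                    row_index=r,
                    col_index=c,
                    origin=(x, y),
                )
            )
    return tiles


def build_training_corpus(
    class_images: Iterable[tuple[RasterImage, str]],
    spec: ChopSpec,
    split_seed: int,
    split_by_parent: bool = False,
) -> LabeledTileCorpus:
    """Chop labeled images into a shuffled, split tile corpus.

    Each tile inherits its parent image's class. The pooled tile list is
    shuffled with ``split_seed`` and the first 75% of the shuffled order is
    assigned to training, the remainder to validation.

    With ``split_by_parent`` the 75/25 split is instead applied to source
    images per class before chopping, so that overlapping near-duplicate
    tiles from one parent can never straddle the train/validation boundary.
    The default mirrors the tile-level protocol.
    """
    images = list(class_images)
    if not images:
        raise ValueError("no input images")
    rng = np.random.default_rng(split_seed)

    if split_by_parent:
        return _build_parent_split(images, spec, split_seed, rng)

    tiles: list[Tile] = []
    labels: list[str] = []
    per_class: dict[str, int] = {}
    for image, label in images:
        new = chop_image(image, spec)
        tiles.extend(new)
        labels.extend([label] * len(new))
        per_class[label] = per_class.get(label, 0) + len(new)
    for cls, n in per_class.items():
        if n == 0:
            raise ValueError(f"class {cls!r} produced zero tiles")
    labels_arr = np.asarray(labels, dtype=object)
    n_total = len(tiles)
    n_train_total = int(np.floor(TRAIN_FRACTION * n_total))
    # stratified split: per-class train counts are the 75% quotas rounded by
    # largest remainder so each class is within one tile of the fraction and
    # the global 75/25 split is exact
    classes = sorted(per_class)
    quotas = {c: TRAIN_FRACTION * per_class[c] for c in classes}
    n_train = {c: int(np.floor(quotas[c])) for c in classes}
    leftover = n_train_total - sum(n_train.values())
    for c in sorted(classes, key=lambda c: quotas[c] - np.floor(quotas[c]), reverse=True):
        if leftover <= 0:
            break
        if n_train[c] < per_class[c]:
            n_train[c] += 1
            leftover -= 1
    split = np.empty(n_total, dtype=object)
    for c in classes:
        idx = np.flatnonzero(labels_arr == c)
        order = rng.permutation(len(idx))
        split[idx[order[: n_train[c]]]] = "train"
        split[idx[order[n_train[c] :]]] = "validation"
    return LabeledTileCorpus(
        tiles=tiles,
        labels=labels_arr,
        split=split,
        split_seed=split_seed,
        class_counts=per_class,
    )


def _build_parent_split(
    images: list[tuple[RasterImage, str]],
    spec: ChopSpec,
    split_seed: int,
    rng: np.random.Generator,
) -> LabeledTileCorpus:
    by_class: dict[str, list[RasterImage]] = {}
    for image, label in images:
        by_class.setdefault(label, []).append(image)
    tiles: list[Tile] = []
    labels: list[str] = []
    split: list[str] = []
    per_class: dict[str, int] = {}
    for cls in sorted(by_class):
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_train = max(1, int(np.floor(TRAIN_FRACTION * len(members)))) if len(members) > 1 else 1
        assignment = {}
        for pos, idx in enumerate(order):
            assignment[idx] = "train" if pos < n_train else "validation"
        count = 0
        for idx, image in enumerate(members):
            new = chop_image(image, spec)
            tiles.extend(new)
            labels.extend([cls] * len(new))
            split.extend([assignment[idx]] * len(new))
            count += len(new)
        if count == 0:
            raise ValueError(f"class {cls!r} produced zero tiles")
        per_class[cls] = count
    return LabeledTileCorpus(
        tiles=tiles,
        labels=np.asarray(labels, dtype=object),
        split=np.asarray(split, dtype=object),
        split_seed=split_seed,
        class_counts=per_class,
    )


def write_corpus(corpus: LabeledTileCorpus, root_path: str | Path) -> Path:
    """Write corpus tiles as lossless PNGs plus a CSV manifest.

    Layout: ``root/<split>/<class>/<parent>_<row>_<col>.png``. Returns the
    manifest path. Round-trips losslessly.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty; nothing to write")
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "split", "parent", "row", "col"])
        for tile, label, split in zip(corpus.tiles, corpus.labels, corpus.split):
            rel = Path(split) / label / f"{tile.parent}_{tile.row_index}_{tile.col_index}.png"
            out = root / rel
            out.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(tile.pixels).save(out)
            writer.writerow(
                [str(rel), label, split, tile.parent, tile.row_index, tile.col_index]
            )
    return manifest
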