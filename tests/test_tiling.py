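"""Chopping arithmetic, corpus construction and on-disk round trips."""

import numpy as np
import pytest
from PIL import Image

from chopmap.raster import RasterImage
from chopmap.tiling import (
    ChopSpec,
    build_training_corpus,
    chop_image,
    tile_count,
    write_corpus,
)


def brute_force_tile_count(length: int, tile_size: int, stride: int) -> int:
    """Independent oracle: enumerate window origins that fit."""
    return sum(1 for origin in range(0, length + 1, stride) if origin + tile_size <= length)


def random_raster(rng, h, w, source_id="img"):
    return RasterImage(rng.integers(0, 256, (h, w, 3), dtype=np.uint8), source_id=source_id)


class TestTileCount:
    @pytest.mark.parametrize(
        "length,tile,overlap,expected",
        [
            (56, 56, 0.0, 1),
            (100, 28, 0.5, 6),  # origins 0,14,...,70; 84 would overrun
            (27, 28, 0.0, 0),
            (27, 28, 0.5, 0),
            (0, 28, 0.0, 0),
        ],
    )
    def test_examples(self, length, tile, overlap, expected):
        assert tile_count(length, ChopSpec(tile, overlap)) == expected

    def test_matches_brute_force_enumeration(self):
        for length in range(65):
            for tile in range(1, 33):
                for overlap in (0.0, 0.25, 0.5, 0.75):
                    spec = ChopSpec(tile, overlap)
                    assert tile_count(length, spec) == brute_force_tile_count(
                        length, tile, spec.stride
                    ), (length, tile, overlap)

    def test_stride_rule(self):
        assert ChopSpec(28, 0.5).stride == 14
        assert ChopSpec(1, 0.9).stride == 1  # floor of one pixel

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ChopSpec(0, 0.0)
        with pytest.raises(ValueError):
            ChopSpec(28, 1.0)


class TestChopImage:
    def test_grid_counts_and_order(self, rng):
        img = random_raster(rng, 100, 100)
        tiles = chop_image(img, ChopSpec(28, 0.5))
        assert len(tiles) == 36
        # row-major order with consistent origins
        for k, t in enumerate(tiles):
            assert (t.row_index, t.col_index) == (k // 6, k % 6)
            assert t.origin == (t.col_index * 14, t.row_index * 14)

    def test_exact_fit_is_identity(self, rng):
        img = random_raster(rng, 56, 56)
        tiles = chop_image(img, ChopSpec(56, 0.0))
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].pixels, img.pixels)

    def test_non_square_image(self, rng):
        img = random_raster(rng, 56, 112)
        tiles = chop_image(img, ChopSpec(56, 0.5))
        assert len(tiles) == 3
        assert [t.origin[0] for t in tiles] == [0, 28, 56]

    def test_windows_are_exact_copies(self, rng):
        img = random_raster(rng, 70, 70)
        for t in chop_image(img, ChopSpec(28, 0.5)):
            x, y = t.origin
            np.testing.assert_array_equal(t.pixels, img.pixels[y : y + 28, x : x + 28])

    def test_undersized_image_gives_empty(self, rng):
        assert chop_image(random_raster(rng, 20, 20), ChopSpec(28)) == []

    def test_no_overlap_reconstruction(self, rng):
        img = random_raster(rng, 90, 70)
        spec = ChopSpec(28, 0.0)
        tiles = chop_image(img, spec)
        rows = []
        for r in range(tile_count(90, spec)):
            rows.append(
                np.hstack([t.pixels for t in tiles if t.row_index == r])
            )
        np.testing.assert_array_equal(np.vstack(rows), img.pixels[:84, :56])

    def test_half_overlap_shares_pixels(self, rng):
        img = random_raster(rng, 56, 56)
        tiles = chop_image(img, ChopSpec(28, 0.5))
        left = next(t for t in tiles if (t.row_index, t.col_index) == (0, 0))
        right = next(t for t in tiles if (t.row_index, t.col_index) == (0, 1))
        np.testing.assert_array_equal(left.pixels[:, 14:], right.pixels[:, :14])


class TestCorpus:
    def _two_class_images(self, rng, size=100):
        return [
            (random_raster(rng, size, size, "a0"), "bamboo"),
            (random_raster(rng, size, size, "b0"), "other"),
        ]

    def test_split_counts(self, rng):
        corpus = build_training_corpus(self._two_class_images(rng), ChopSpec(28, 0.5), 0)
        assert len(corpus) == 72
        assert int(np.sum(corpus.split == "train")) == 54
        assert int(np.sum(corpus.split == "validation")) == 18
        assert corpus.class_counts == {"bamboo": 36, "other": 36}
        # per-class split within one tile of 75%
        for cls in ("bamboo", "other"):
            n_train = int(np.sum((corpus.split == "train") & (corpus.labels == cls)))
            assert abs(n_train - 0.75 * 36) <= 1

    def test_split_deterministic_and_seed_sensitive(self, rng):
        images = self._two_class_images(rng)
        c1 = build_training_corpus(images, ChopSpec(28, 0.5), 42)
        c2 = build_training_corpus(images, ChopSpec(28, 0.5), 42)
        c3 = build_training_corpus(images, ChopSpec(28, 0.5), 43)
        np.testing.assert_array_equal(c1.split, c2.split)
        assert not np.array_equal(c1.split, c3.split)

    def test_minimal_corpus_keeps_a_training_tile(self, rng):
        images = [
            (random_raster(rng, 56, 56, "a"), "bamboo"),
            (random_raster(rng, 56, 56, "b"), "other"),
        ]
        corpus = build_training_corpus(images, ChopSpec(56, 0.0), 0)
        assert len(corpus) == 2
        assert int(np.sum(corpus.split == "train")) == 1
        assert int(np.sum(corpus.split == "validation")) == 1

    def test_zero_tile_class_raises_with_name(self, rng):
        images = [
            (random_raster(rng, 100, 100, "a"), "bamboo"),
            (random_raster(rng, 20, 20, "b"), "other"),
        ]
        with pytest.raises(ValueError, match="other"):
            build_training_corpus(images, ChopSpec(28, 0.5), 0)

    def test_split_by_parent_keeps_parents_whole(self, rng):
        images = [
            (random_raster(rng, 100, 100, f"{cls}{i}"), cls)
            for cls in ("bamboo", "other")
            for i in range(4)
        ]
        corpus = build_training_corpus(
            images, ChopSpec(28, 0.5), 0, split_by_parent=True
        )
        for parent in {t.parent for t in corpus.tiles}:
            idx = [i for i, t in enumerate(corpus.tiles) if t.parent == parent]
            assert len({corpus.split[i] for i in idx}) == 1


class TestWriteCorpus:
    def test_round_trip(self, rng, tmp_path):
        images = [
            (random_raster(rng, 100, 100, "a0"), "bamboo"),
            (random_raster(rng, 100, 100, "b0"), "other"),
        ]
        corpus = build_training_corpus(images, ChopSpec(28, 0.5), 0)
        manifest = write_corpus(corpus, tmp_path)
        lines = manifest.read_text().strip().splitlines()
        assert lines[0] == "path,class,split,parent,row,col"
        assert len(lines) == 73
        pngs = sorted(tmp_path.rglob("*.png"))
        assert len(pngs) == 72
        # spot-check lossless round trip on every tile
        for tile, label, split in zip(corpus.tiles, corpus.labels, corpus.split):
            path = tmp_path / split / label / f"{tile.parent}_{tile.row_index}_{tile.col_index}.png"
            np.testing.assert_array_equal(np.asarray(Image.open(path)), tile.pixels)

    def test_empty_corpus_raises(self, rng, tmp_path):
        corpus = build_training_corpus(
            [
                (random_raster(rng, 56, 56, "a"), "bamboo"),
                (random_raster(rng, 56, 56, "b"), "other"),
            ],
            ChopSpec(56, 0.0),
            0,
        )
        corpus.tiles, corpus.labels, corpus.split = [], corpus.labels[:0], corpus.split[:0]
        with pytest.raises(ValueError):
            write_corpus(corpus, tmp_path / "out")
        assert not (tmp_path / "out").exists() or not any((tmp_path / "out").iterdir())
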