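"""Raster image container and plain-file IO.

A :class:`RasterImage` is the unit of acquisition and mapping: an H x W x 3
uint8 pixel array with an optional nominal spatial resolution in metres per
pixel and an opaque source identifier used for tile provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["RasterImage", "read_raster", "write_raster"]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class RasterImage:
    """An RGB raster with optional nominal resolution metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array; values are clipped-representable in ``[0, 255]``
        and stored as ``uint8``.
    resolution_m_per_px
        Nominal ground resolution in metres per pixel, or ``None`` when
        unknown. Purely informational; no georeferencing is implied.
    source_id
        Opaque identifier naming where the raster came from (file stem,
        synthetic-scene tag, ...). Inherited by tiles cut from this raster.
    """

    pixels: np.ndarray
    resolution_m_per_px: float | None = None
    source_id: str = field(default="raster")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("raster must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.resolution_m_per_px is not None and self.resolution_m_per_px <= 0:
            raise ValueError("resolution_m_per_px must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def read_raster(
    path: str | Path, resolution_m_per_px: float | None = None
) -> RasterImage:
    """Read a PNG/JPEG/TIFF file as an RGB raster.

    TIFFs are read through :mod:`tifffile`; only the first three bands are
    kept. Greyscale inputs are replicated across the three channels.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return RasterImage(arr, resolution_m_per_px=resolution_m_per_px, source_id=path.stem)


def write_raster(image: RasterImage, path: str | Path) -> Path:
    """Write a raster losslessly (PNG or TIFF depending on suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels).save(path)
    return path
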