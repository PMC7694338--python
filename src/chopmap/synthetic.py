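"""Synthetic aerial-scene generator for two-class texture experiments.

Stands in for downloaded satellite/aerial imagery so every experiment runs
offline. The generator emulates the statistical structure the method
relies on:

* **bamboo** — a fine-scale, high-frequency texture with a dominant
  orientation (wavy sinusoidal stripes plus speckle) in a yellow-green
  hue, mimicking the quasi-periodic culm/canopy pattern seen from above;
* **other** classes — a coarse blob canopy, a smooth gradient meadow, or
  a blocky urban mosaic, none of which carry the oriented high-frequency
  signature (colour alone never separates the classes, so both the
  convolutional classifier and the GLCM baseline have genuine texture
  signal to find);
* **zoom levels** — block-mean downsampling by factors 1/2/4 emulates
  acquisition at ~0.13 / ~0.26 / ~0.65 m per pixel;
* **site styles** — deterministic hue shifts, brightness offsets and blur
  emulate site-to-site appearance differences (weather, season, sensor).

Everything is reproducible: an image is a pure function of its parameters
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster import RasterImage

__all__ = [
    "TextureParams",
    "SiteStyle",
    "CLASS_PRESETS",
    "SITE_STYLES",
    "generate_class_image",
    "apply_style",
    "generate_site",
    "downsample_scene",
]

MIN_DIM = 64
BASE_RESOLUTION_M_PER_PX = 0.13  # emulated finest zoom level


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one synthetic land-cover texture."""

    name: str
    pattern: str  # oriented_stripes | coarse_blobs | smooth_gradient | block_mosaic
    base_color: tuple[float, float, float]
    hue_jitter: float = 12.0  # per-channel uniform jitter, pixel levels
    orientation_deg: float = 45.0
    wavelength_px: float = 6.0
    amplitude: float = 40.0  # texture amplitude, pixel levels
    correlation_px: float = 12.0
    contrast: float = 1.0


CLASS_PRESETS: dict[str, TextureParams] = {
    "bamboo": TextureParams(
        name="bamboo",
        pattern="oriented_stripes",
        base_color=(120.0, 150.0, 70.0),
        orientation_deg=45.0,
        wavelength_px=6.0,
        amplitude=40.0,
    ),
    "canopy": TextureParams(
        name="canopy",
        pattern="coarse_blobs",
        base_color=(70.0, 110.0, 60.0),
        correlation_px=12.0,
        amplitude=35.0,
    ),
    "meadow": TextureParams(
        name="meadow",
        pattern="smooth_gradient",
        base_color=(130.0, 150.0, 90.0),
        amplitude=30.0,
    ),
    "urban": TextureParams(
        name="urban",
        pattern="block_mosaic",
        base_color=(150.0, 145.0, 140.0),
        amplitude=50.0,
    ),
}


@dataclass(frozen=True)
class SiteStyle:
    """Deterministic appearance transform emulating one acquisition site."""

    hue_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brightness: float = 0.0
    blur_radius: float = 0.0

    def is_identity(self) -> bool:
        return self.hue_shift == (0.0, 0.0, 0.0) and self.brightness == 0 and self.blur_radius == 0


SITE_STYLES: dict[str, SiteStyle] = {
    "site_a": SiteStyle(),
    "site_b": SiteStyle(hue_shift=(14.0, -6.0, -10.0), brightness=12.0),
    "site_c": SiteStyle(hue_shift=(-10.0, 6.0, 14.0), brightness=-10.0, blur_radius=1.0),
}


def generate_class_image(
    params: TextureParams, width: int, height: int, seed: int
) -> RasterImage:
    """Render one class-pure synthetic scene; a pure function of the seed."""
    if width < MIN_DIM or height < MIN_DIM:
        raise ValueError(f"dimensions must be at least {MIN_DIM} pixels")
    rng = np.random.default_rng(seed)
    if params.pattern == "oriented_stripes":
        field = _oriented_stripes(params, width, height, rng)
    elif params.pattern == "coarse_blobs":
        field = _coarse_blobs(params, width, height, rng)
    elif params.pattern == "smooth_gradient":
        field = _smooth_gradient(params, width, height, rng)
    elif params.pattern == "block_mosaic":
        field = _block_mosaic(params, width, height, rng)
    else:
        raise ValueError(f"unknown texture pattern {params.pattern!r}")
    base = np.asarray(params.base_color) + rng.uniform(
        -params.hue_jitter, params.hue_jitter, 3
    )
    img = base[None, None, :] + params.contrast * field[:, :, None]
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(
        img,
        resolution_m_per_px=BASE_RESOLUTION_M_PER_PX,
        source_id=f"{params.name}_{seed}",
    )


def _grid(width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))


def _oriented_stripes(p: TextureParams, w: int, h: int, rng) -> np.ndarray:
    x, y = _grid(w, h)
    theta = np.deg2rad(p.orientation_deg + rng.uniform(-10, 10))
    t = x * np.cos(theta) + y * np.sin(theta)
    # smooth phase noise makes the stripes wavy rather than ruled
    phase = gaussian_filter(rng.standard_normal((h, w)), sigma=8.0) * 6.0
    stripes = np.sin(2.0 * np.pi * t / p.wavelength_px + phase)
    speckle = rng.normal(0.0, 0.3, (h, w))
    return p.amplitude * (stripes + speckle)


def _coarse_blobs(p: TextureParams, w: int, h: int, rng) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal((h, w)), sigma=p.correlation_px)
    g = g / max(g.std(), 1e-9)
    return p.amplitude * g


def _smooth_gradient(p: TextureParams, w: int, h: int, rng) -> np.ndarray:
    x, y = _grid(w, h)
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (x * np.cos(theta) + y * np.sin(theta)) / max(w, h)
    ramp = ramp - ramp.mean()
    slow = gaussian_filter(rng.standard_normal((h, w)), sigma=32.0)
    slow = slow / max(slow.std(), 1e-9)
    return p.amplitude * (ramp + 0.3 * slow)


def _block_mosaic(p: TextureParams, w: int, h: int, rng) -> np.ndarray:
    block = int(rng.integers(16, 49))
    nb_h, nb_w = -(-h // block), -(-w // block)
    values = rng.uniform(-1.0, 1.0, (nb_h, nb_w))
    field = np.repeat(np.repeat(values, block, axis=0), block, axis=1)[:h, :w]
    return p.amplitude * field


def apply_style(image: RasterImage, style: SiteStyle) -> RasterImage:
    """Apply a site's appearance transform (blur, then hue/brightness)."""
    arr = image.pixels.astype(float)
    if style.blur_radius > 0:
        arr = np.stack(
            [gaussian_filter(arr[:, :, c], sigma=style.blur_radius) for c in range(3)],
            axis=2,
        )
    arr = arr + np.asarray(style.hue_shift)[None, None, :] + style.brightness
    return RasterImage(
        np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8),
        resolution_m_per_px=image.resolution_m_per_px,
        source_id=image.source_id,
    )


def generate_site(
    site_id: str,
    style: SiteStyle,
    n_images_per_class: int,
    dims: int,
    seed: int,
    classes: dict[str, TextureParams] | None = None,
) -> tuple[list[tuple[RasterImage, str]], pd.DataFrame]:
    """Labeled class-pure images for one emulated acquisition site.

    Returns ``(images, manifest)`` where ``images`` is a list of
    ``(RasterImage, class_label)`` and the manifest records site, class,
    index and the per-image seed so the collection can be regenerated
    bit-identically.
    """
    if n_images_per_class < 1:
        raise ValueError("need at least one image per class")
    if classes is None:
        classes = {"bamboo": CLASS_PRESETS["bamboo"], "other": CLASS_PRESETS["canopy"]}
    rng = np.random.default_rng(seed)
    images: list[tuple[RasterImage, str]] = []
    records = []
    for label in sorted(classes):
        params = replace(classes[label], name=label)
        for i in range(n_images_per_class):
            child = int(rng.integers(0, 2**31 - 1))
            img = generate_class_image(params, dims, dims, child)
            img = apply_style(img, style)
            img.source_id = f"{site_id}_{label}_{i}"
            images.append((img, label))
            records.append({"site": site_id, "class": label, "index": i, "seed": child})
    return images, pd.DataFrame.from_records(records)


def downsample_scene(image: RasterImage, factor: int) -> RasterImage:
    """Block-mean downsampling emulating coarser acquisition zoom levels.

    Factor 1 is identity; factors 2 and 4 halve/quarter the linear
    resolution (block means, rounded half-up). The nominal metres-per-pixel
    metadata is multiplied by the factor.
    """
    if factor not in (1, 2, 4):
        raise ValueError("factor must be one of 1, 2, 4")
    if factor == 1:
        return RasterImage(
            image.pixels.copy(), image.resolution_m_per_px, image.source_id
        )
    h, w = image.height, image.width
    if h % factor or w % factor:
        raise ValueError(f"dimensions {h}x{w} not divisible by factor {factor}")
    arr = image.pixels.astype(float).reshape(h // factor, factor, w // factor, factor, 3)
    mean = arr.mean(axis=(1, 3))
    res = image.resolution_m_per_px
    return RasterImage(
        np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8),
        resolution_m_per_px=None if res is None else res * factor,
        source_id=f"{image.source_id}_f{factor}",
    )
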