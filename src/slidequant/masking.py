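"""Binary keep/hide masks over a low-magnification slide layer.

A mask marks which part of the slide is analyzed (keep, stored white) and
which is hidden (background and artifacts, stored black). Masks are generated
automatically from a miniature layer — blur, then a fuzzy selection of the
near-white scanner background — and can be round-tripped through an external
image editor for manual cleanup (air bubbles, pen marks, control tissue).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .slide_io import Layer

__all__ = ["Mask", "generate_mask", "save_mask", "load_mask", "scale_mask", "REFERENCE_WHITE"]

#: Scanner background reference color. Backgrounds are near-white; an
#: estimate from the modal border color may replace this via ``generate_mask``.
REFERENCE_WHITE = (255, 255, 255)

#: Largest possible Euclidean RGB distance from reference white (to black).
_MAX_DISTANCE = float(np.sqrt(3.0) * 255.0)


@dataclass
class Mask:
    """Binary raster: ``True`` = keep (analyze), ``False`` = hide."""

    pixels: np.ndarray  # (H, W) bool
    source_magnification: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def keep_fraction(self) -> float:
        return float(self.pixels.mean())


def estimate_reference_white(layer: Layer, border: int = 4) -> tuple[int, int, int]:
    """Modal color of the layer border, a proxy for the scanner background."""
    px = layer.pixels
    edge = np.concatenate(
        [
            px[:border].reshape(-1, 3),
            px[-border:].reshape(-1, 3),
            px[:, :border].reshape(-1, 3),
            px[:, -border:].reshape(-1, 3),
        ]
    )
    colors, counts = np.unique(edge, axis=0, return_counts=True)
    return tuple(int(c) for c in colors[np.argmax(counts)])


def generate_mask(
    layer: Layer,
    blur_sigma: float = 2.0,
    fuzz: float = 0.10,
    reference_white: tuple[int, int, int] = REFERENCE_WHITE,
    min_region: int = 50,
) -> Mask:
    """Create a keep/hide mask from a miniature layer.

    The layer is Gaussian-blurred (removes dust and speckle), then every pixel
    whose blurred color lies within Euclidean RGB distance ``fuzz * max``
    of ``reference_white`` is hidden — a fuzzy, non-stringent selection of the
    white background. Keep-regions smaller than ``min_region`` pixels (at mask
    scale) are dropped as speckle.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if not 0 <= fuzz < 1:
        raise ValueError("fuzz must lie in [0, 1)")
    rgb = layer.pixels.astype(np.float64)
    if blur_sigma > 0:
        rgb = ndimage.gaussian_filter(rgb, sigma=(blur_sigma, blur_sigma, 0))
    dist = np.sqrt(((rgb - np.asarray(reference_white, dtype=np.float64)) ** 2).sum(axis=2))
    keep = dist > fuzz * _MAX_DISTANCE
    if min_region > 0 and keep.any():
        labels, n = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_region)
        keep &= ~np.isin(labels, small[small > 0])
    return Mask(keep, source_magnification=layer.magnification)


def save_mask(mask: Mask, path: str | os.PathLike) -> Path:
    """Write a mask as an 8-bit PNG, white = keep, black = hide."""
    path = Path(path)
    iio.imwrite(path, np.where(mask.pixels, 255, 0).astype(np.uint8))
    return path


def load_mask(
    path: str | os.PathLike,
    expected_shape: tuple[int, int],
    source_magnification: float = 0.0,
) -> Mask:
    """Load a (possibly hand-edited) mask image, binarizing at 50% luminance.

    ``expected_shape`` guards against mask/slide mix-ups: a mask painted over
    the wrong slide, or at the wrong pyramid level, fails loudly here instead
    of silently mis-masking the analysis.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64).mean(axis=2)
    else:
        arr = arr.astype(np.float64)
    if arr.shape != tuple(expected_shape):
        raise ValueError(
            f"mask shape {arr.shape} does not match expected layer shape "
            f"{tuple(expected_shape)} ({path})"
        )
    limit = 255.0 if arr.max() > 1.0 else 1.0
    return Mask(arr >= 0.5 * limit, source_magnification=source_magnification)


def _nearest_indices(target: int, source: int) -> np.ndarray:
    # pixel-center mapping: target pixel i samples source pixel floor((i+0.5)*s/t)
    return np.minimum(((np.arange(target) + 0.5) * source / target).astype(np.intp), source - 1)


def scale_mask(mask: Mask, target_width: int, target_height: int) -> Mask:
    """Nearest-neighbor rescale of a binary mask to a new geometry.

    Used to lay the miniature-layer mask over a high-magnification layer.
    Target aspect must match the mask's within 1%.
    """
    if target_width < 1 or target_height < 1:
        raise ValueError("target size must be >= 1 pixel")
    h, w = mask.shape
    if abs((target_width / target_height) / (w / h) - 1.0) > 0.01:
        raise ValueError(
            f"target aspect {target_width}x{target_height} does not match "
            f"mask aspect {w}x{h}"
        )
    rows = _nearest_indices(target_height, h)
    cols = _nearest_indices(target_width, w)
    scaled = mask.pixels[np.ix_(rows, cols)]
    scale = target_width / w
    return Mask(scaled, source_magnification=mask.source_magnification * scale)
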