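"""Mask-aware tiling of a high-magnification layer.

Whole 20x layers are too large to analyze in one piece, so the layer is cut
into a grid of square tiles (edge tiles may be smaller). The low-magnification
mask is laid over the layer; tiles whose keep-fraction falls below a threshold
are excluded, and hidden pixels inside emitted tiles are filled with the
reference background white so they contribute no optical density downstream.
Tiles are written as lossless PNG next to a CSV manifest.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .masking import Mask, REFERENCE_WHITE, _nearest_indices
from .slide_io import Layer

__all__ = ["TileEntry", "TilePlan", "Tile", "plan_tiles", "extract_tiles", "iter_tiles"]

DEFAULT_TILE_SIZE = 2048
DEFAULT_MIN_KEEP = 0.01

MANIFEST_COLUMNS = [
    "row", "col", "x0", "y0", "width", "height", "keep_fraction", "filename",
]


@dataclass(frozen=True)
class TileEntry:
    row: int
    col: int
    x0: int
    y0: int
    width: int
    height: int
    keep_fraction: float
    included: bool

    @property
    def filename(self) -> str:
        return f"tile_r{self.row}_c{self.col}.png"


@dataclass
class TilePlan:
    """Grid plan over one layer; entries partition the layer exactly."""

    tile_size: int
    grid_rows: int
    grid_cols: int
    layer_width: int
    layer_height: int
    entries: list[TileEntry]

    @property
    def included(self) -> list[TileEntry]:
        return [e for e in self.entries if e.included]


@dataclass
class Tile:
    """Pixels of one included plan entry, hidden pixels filled with white."""

    entry: TileEntry
    pixels: np.ndarray  # (h, w, 3) uint8


def _mask_patch(mask: Mask, entry_or_rect, layer_w: int, layer_h: int) -> np.ndarray:
    """Nearest-neighbor sample of the mask over one tile rectangle.

    Equivalent to upscaling the whole mask to the layer geometry and cropping,
    but touches only O(tile area) memory.
    """
    x0, y0, w, h = entry_or_rect
    mh, mw = mask.shape
    rows = np.minimum(((np.arange(y0, y0 + h) + 0.5) * mh / layer_h).astype(np.intp), mh - 1)
    cols = np.minimum(((np.arange(x0, x0 + w) + 0.5) * mw / layer_w).astype(np.intp), mw - 1)
    return mask.pixels[np.ix_(rows, cols)]


def plan_tiles(
    layer: Layer,
    mask: Mask | None,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_keep: float = DEFAULT_MIN_KEEP,
) -> TilePlan:
    """Plan a ceil(W/T) x ceil(H/T) grid; mark low-coverage tiles excluded.

    Without a mask every tile has keep_fraction 1 and is included.
    """
    if tile_size < 64:
        raise ValueError(f"tile_size must be >= 64, got {tile_size}")
    if not 0 <= min_keep <= 1:
        raise ValueError("min_keep must lie in [0, 1]")
    W, H = layer.width, layer.height
    if mask is not None:
        mh, mw = mask.shape
        if abs((mw / mh) / (W / H) - 1.0) > 0.01:
            raise ValueError(
                f"mask aspect {mw}x{mh} does not match layer aspect {W}x{H}"
            )
    cols = math.ceil(W / tile_size)
    rows = math.ceil(H / tile_size)
    entries: list[TileEntry] = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * tile_size, r * tile_size
            w = min(tile_size, W - x0)
            h = min(tile_size, H - y0)
            if mask is None:
                kf = 1.0
            else:
                kf = float(_mask_patch(mask, (x0, y0, w, h), W, H).mean())
            entries.append(
                TileEntry(r, c, x0, y0, w, h, keep_fraction=kf, included=kf >= min_keep)
            )
    return TilePlan(
        tile_size=tile_size,
        grid_rows=rows,
        grid_cols=cols,
        layer_width=W,
        layer_height=H,
        entries=entries,
    )


def iter_tiles(layer: Layer, plan: TilePlan, mask: Mask | None):
    """Yield :class:`Tile` objects for the plan's included entries.

    Hidden pixels are composited to reference white (not black: black would
    read as maximal optical density and be mistaken for tissue downstream).
    """
    if plan.layer_width != layer.width or plan.layer_height != layer.height:
        raise ValueError("plan was built for a layer of different geometry")
    white = np.asarray(REFERENCE_WHITE, dtype=np.uint8)
    for entry in plan.included:
        patch = layer.pixels[
            entry.y0 : entry.y0 + entry.height, entry.x0 : entry.x0 + entry.width
        ]
        if mask is not None:
            keep = _mask_patch(
                mask, (entry.x0, entry.y0, entry.width, entry.height),
                layer.width, layer.height,
            )
            patch = np.where(keep[..., None], patch, white[None, None, :])
        yield Tile(entry=entry, pixels=np.ascontiguousarray(patch))


def extract_tiles(
    layer: Layer,
    plan: TilePlan,
    mask: Mask | None,
    out_dir: str | os.PathLike,
) -> Path:
    """Write included tiles as lossless PNGs plus a CSV manifest.

    Re-running over an existing directory overwrites deterministically.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for tile in iter_tiles(layer, plan, mask):
        iio.imwrite(out_dir / tile.entry.filename, tile.pixels)
        e = tile.entry
        records.append(
            (e.row, e.col, e.x0, e.y0, e.width, e.height, e.keep_fraction, e.filename)
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
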