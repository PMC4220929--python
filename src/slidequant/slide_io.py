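"""Pyramid TIFF slide reading, writing, layer selection and naming.

A whole-slide image (WSI) is stored as a multi-page "pyramid" TIFF: the same
scene rasterized at successively lower magnifications (e.g. 40x, 20x, 1.25x).
This module reads such files into :class:`PyramidSlide`, writes lossless
pyramids for synthetic fixtures, selects the working layer for a target
magnification, extracts scanner metadata and enforces the
``<study_number>.<stain>.tif`` naming convention.

Coordinate convention throughout the package: row-major, 0-based, origin at
the top-left, half-open pixel intervals.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "Layer",
    "SlideMetadata",
    "SlideName",
    "PyramidSlide",
    "SlideFormatError",
    "read_pyramid",
    "write_pyramid",
    "select_layer",
    "extract_metadata",
    "rename_slide",
    "make_thumbnail",
]

#: Nominal magnification assigned to the largest page when the file carries
#: no magnification information (scanner default for the supported slides).
DEFAULT_NOMINAL_MAGNIFICATION = 40.0


class SlideFormatError(ValueError):
    """Raised when a TIFF file does not describe a valid RGB pyramid."""


@dataclass
class Layer:
    """One pyramid level: an 8-bit RGB raster plus its magnification."""

    pixels: np.ndarray  # (H, W, 3) uint8
    magnification: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SlideFormatError(
                f"layer raster must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise SlideFormatError(f"layer raster must be uint8, got {self.pixels.dtype}")
        if self.width < 1 or self.height < 1:
            raise SlideFormatError("layer must be at least 1x1 pixel")
        if not self.magnification > 0:
            raise SlideFormatError("magnification must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class SlideMetadata:
    """Scanner metadata; absent TIFF tags stay ``None``, never invented."""

    pixels_per_micrometer: float | None = None
    scan_date: datetime | None = None
    compression: str | None = None
    layer_count: int = 0


@dataclass(frozen=True)
class SlideName:
    """``<study_number>.<stain>.tif`` naming convention (e.g. AAA100.CD3.tif)."""

    study_number: str
    stain: str

    def __post_init__(self) -> None:
        for label, value in (("study_number", self.study_number), ("stain", self.stain)):
            if not value:
                raise ValueError(f"{label} must be non-empty")
            if "." in value:
                raise ValueError(f"{label} must not contain '.': {value!r}")

    def filename(self) -> str:
        return f"{self.study_number}.{self.stain}.tif"


@dataclass
class PyramidSlide:
    """Ordered pyramid of RGB layers, strictly decreasing magnification."""

    layers: list[Layer]
    metadata: SlideMetadata = field(default_factory=SlideMetadata)
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise SlideFormatError("a slide needs at least one layer")
        mags = [lay.magnification for lay in self.layers]
        if any(a <= b for a, b in zip(mags, mags[1:])):
            raise SlideFormatError(f"layer magnifications must strictly decrease, got {mags}")

    @property
    def magnifications(self) -> list[float]:
        return [lay.magnification for lay in self.layers]


def read_pyramid(
    path: str | os.PathLike,
    nominal_magnification: float = DEFAULT_NOMINAL_MAGNIFICATION,
) -> PyramidSlide:
    """Read a multi-page TIFF into a :class:`PyramidSlide`.

    Pages lacking magnification tags are assigned a magnification from their
    width ratio to the largest page, which is pinned at
    ``nominal_magnification`` (the scan setting; default 40).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            if not pages:
                raise SlideFormatError(f"{path}: TIFF contains no image pages")
            rasters = []
            for i, page in enumerate(pages):
                arr = page.asarray()
                if arr.ndim != 3 or arr.shape[-1] != 3 or arr.dtype != np.uint8:
                    raise SlideFormatError(
                        f"{path}: page {i} is not 8-bit RGB (shape {arr.shape}, {arr.dtype})"
                    )
                rasters.append(arr)
            tagged = _parse_magnifications(pages[0].description, len(pages))
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc

    if tagged is not None:
        layers = [Layer(arr, magnification=m) for arr, m in zip(rasters, tagged)]
    else:
        top_width = max(arr.shape[1] for arr in rasters)
        layers = [
            Layer(arr, magnification=nominal_magnification * arr.shape[1] / top_width)
            for arr in rasters
        ]
    layers.sort(key=lambda lay: -lay.magnification)
    meta = extract_metadata(path)
    return PyramidSlide(layers=layers, metadata=meta, source_name=path.name)


def _parse_magnifications(description: str | None, n_pages: int) -> list[float] | None:
    """Magnifications from the first page's ImageDescription, if we wrote them.

    Tag precedence (ImageDescription before size-ratio inference) is fixed
    here; files from other scanners simply fall through to inference.
    """
    if not description:
        return None
    try:
        data = json.loads(description)
        mags = [float(m) for m in data["magnifications"]]
    except (ValueError, TypeError, KeyError):
        return None
    if len(mags) != n_pages or any(m <= 0 for m in mags):
        return None
    return mags


def write_pyramid(
    layers: list[Layer],
    metadata: SlideMetadata | None,
    path: str | os.PathLike,
) -> Path:
    """Write layers as a lossless multi-page TIFF readable by :func:`read_pyramid`.

    Layers must already be ordered by decreasing magnification. Pixel content
    round-trips bit-identically (Deflate compression, no chroma loss).
    """
    if not layers:
        raise ValueError("cannot write a pyramid with zero layers")
    mags = [lay.magnification for lay in layers]
    if any(a <= b for a, b in zip(mags, mags[1:])):
        raise ValueError(f"layers must be ordered by decreasing magnification, got {mags}")
    path = Path(path)
    description = json.dumps({"magnifications": mags})
    kwargs: dict = {}
    if metadata is not None and metadata.pixels_per_micrometer is not None:
        # TIFF resolution in pixels per centimeter (10^4 µm per cm).
        ppcm = metadata.pixels_per_micrometer * 1e4
        kwargs["resolution"] = (ppcm, ppcm)
        kwargs["resolutionunit"] = "CENTIMETER"
    if metadata is not None and metadata.scan_date is not None:
        kwargs["datetime"] = metadata.scan_date
    try:
        with tifffile.TiffWriter(path) as writer:
            for i, lay in enumerate(layers):
                writer.write(
                    lay.pixels,
                    photometric="rgb",
                    compression="deflate",
                    description=description if i == 0 else None,
                    **kwargs,
                )
    except OSError as exc:
        raise OSError(f"cannot write TIFF {path}: {exc}") from exc
    return path


def select_layer(slide: PyramidSlide, target_magnification: float) -> Layer:
    """Return the layer closest to ``target_magnification`` in log-ratio.

    Magnification is a multiplicative scale, so closeness is measured as
    ``|log(m / target)|``; ties break toward the higher magnification.
    """
    if not target_magnification > 0:
        raise ValueError("target magnification must be positive")
    return min(
        slide.layers,
        key=lambda lay: (
            abs(math.log(lay.magnification / target_magnification)),
            -lay.magnification,
        ),
    )


def _parse_tiff_datetime(value) -> datetime | None:
    if isinstance(value, datetime):
        return value
    if isinstance(value, bytes):
        value = value.decode("ascii", "replace")
    if isinstance(value, str):
        for fmt in ("%Y:%m:%d %H:%M:%S", "%Y-%m-%dT%H:%M:%S"):
            try:
                return datetime.strptime(value.strip().rstrip("\x00"), fmt)
            except ValueError:
                continue
    return None


def extract_metadata(path: str | os.PathLike) -> SlideMetadata:
    """Read slide metadata (resolution, scan date, compression, layer count).

    Fields whose TIFF tags are absent remain ``None``.
    """
    path = Path(path)
    meta = SlideMetadata()
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            meta.layer_count = len(pages)
            if not pages:
                return meta
            page = pages[0]
            tags = page.tags
            xres = tags.get("XResolution")
            unit = tags.get("ResolutionUnit")
            if xres is not None and unit is not None:
                num, den = xres.value
                if den and num:
                    per_unit = num / den
                    unit_name = getattr(unit.value, "name", str(unit.value)).upper()
                    per_um = {
                        "CENTIMETER": per_unit / 1e4,
                        "3": per_unit / 1e4,
                        "INCH": per_unit / 25400.0,
                        "2": per_unit / 25400.0,
                    }.get(unit_name)
                    if per_um:
                        meta.pixels_per_micrometer = per_um
            dt = tags.get("DateTime")
            if dt is not None:
                meta.scan_date = _parse_tiff_datetime(dt.value)
            comp = tags.get("Compression")
            if comp is not None:
                meta.compression = getattr(comp.value, "name", str(comp.value))
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    return meta


def rename_slide(path: str | os.PathLike, name: SlideName, dry_run: bool = False) -> Path:
    """Rename a slide file to the ``studynumber.stain.tif`` convention.

    Refuses to overwrite an existing destination; with ``dry_run`` the target
    path is computed and returned without touching the filesystem.
    """
    path = Path(path)
    target = path.with_name(name.filename())
    if target == path:
        return target
    if target.exists():
        raise FileExistsError(f"refusing to overwrite {target} while renaming {path}")
    if not dry_run:
        if not path.exists():
            raise FileNotFoundError(f"no such slide: {path}")
        path.rename(target)
    return target


def make_thumbnail(slide: PyramidSlide, max_edge: int = 512) -> Layer:
    """Downscale the lowest-magnification layer so max(w, h) <= ``max_edge``."""
    if max_edge < 16:
        raise ValueError(f"max_edge must be >= 16, got {max_edge}")
    lay = slide.layers[-1]
    longest = max(lay.width, lay.height)
    if longest <= max_edge:
        return lay
    scale = max_edge / longest
    new_w = max(1, round(lay.width * scale))
    new_h = max(1, round(lay.height * scale))
    img = Image.fromarray(lay.pixels).resize((new_w, new_h), Image.BILINEAR)
    return Layer(np.asarray(img, dtype=np.uint8), magnification=lay.magnification * scale)
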