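"""Synthetic whole-slide renderer with known ground truth.

Renders pyramid slides that emulate DAB/hematoxylin immunostains on a white
scanner background: smooth tissue blobs carrying a hematoxylin counterstain,
DAB-stained nuclei (isolated and in touching clumps), and maskable artifacts
(air bubble, coverslip shadow, pen mark). Pixels follow a Beer–Lambert
transmission model, I_c = I0_c * 10^(-sum_s c_s * v_{s,c}), with Gaussian
sensor noise added afterwards, so stain unmixing with the same basis is the
exact inverse of the renderer up to noise.

Geometry notes. The canvas is the top pyramid layer, rendered at the working
analysis magnification (default 20x) so nucleus diameters are specified in
the same pixels the detection gate sees; lower levels are exact 2x and 32x
block means. Nuclei composite into the DAB concentration field with a
pointwise max (cells exclude each other spatially rather than stacking
optically), and carry a mild radial density profile peaking at the center —
this is what makes touching clump members separable by intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .detection import StainBasis
from .slide_io import Layer, PyramidSlide, SlideMetadata

__all__ = [
    "SyntheticSlideSpec",
    "GroundTruth",
    "render_slide",
    "add_artifacts",
    "render_replicate",
    "block_mean_downsample",
]

ARTIFACT_KINDS = ("air_bubble", "coverslip_shadow", "pen_mark")

#: Central density boost of the radial nucleus profile: OD runs from dab_od
#: at the rim to (1 + bump) * dab_od at the center.
NUCLEUS_CENTER_BUMP = 0.3


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Study conditions for one rendered slide. Deterministic per seed."""

    seed: int = 0
    canvas: tuple[int, int] = (1024, 1024)  # (width, height), top layer
    top_magnification: float = 20.0
    tissue_blobs: int = 2
    tissue_smoothness: float = 40.0  # px, blob length scale
    tissue_coverage: float = 0.35  # target keep fraction before blob pruning
    hematoxylin_od: float = 0.3
    nucleus_count: int = 50
    nucleus_diameter_range: tuple[float, float] = (8.0, 24.0)
    dab_od: float = 0.8
    clump_fraction: float = 0.0  # fraction of nuclei placed in touching pairs
    noise_sigma: float = 0.0  # intensity units (0-255)
    artifacts: tuple[str, ...] = ()
    pixels_per_micrometer: float = 2.0

    def __post_init__(self) -> None:
        w, h = self.canvas
        if w % 32 or h % 32 or w < 64 or h < 64:
            raise ValueError("canvas sides must be multiples of 32 and >= 64")
        lo, hi = self.nucleus_diameter_range
        if not (0 < lo <= hi < min(w, h) / 4):
            raise ValueError("nucleus diameters must lie in (0, canvas/4)")
        if not 0 <= self.clump_fraction <= 1:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if not 0 < self.tissue_coverage < 1:
            raise ValueError("tissue_coverage must lie in (0, 1)")
        bad = set(self.artifacts) - set(ARTIFACT_KINDS)
        if bad:
            raise ValueError(f"unknown artifacts: {sorted(bad)}")


@dataclass
class GroundTruth:
    """What was rendered: nucleus geometry, tissue area, artifact regions."""

    positions: np.ndarray  # (N, 2) float, (x, y) at top-layer scale
    diameters: np.ndarray  # (N,) float px
    tissue_area: int  # px at top-layer scale
    artifact_regions: dict = field(default_factory=dict)  # kind -> (x0, y0, x1, y1)
    spec: SyntheticSlideSpec | None = None

    @property
    def count(self) -> int:
        return len(self.positions)


class PlacementError(RuntimeError):
    """Nucleus placement failed; the spec is overcrowded for its canvas."""


def block_mean_downsample(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Exact factor-x area-mean downsample of an (H, W, 3) uint8 raster."""
    h, w = pixels.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"raster {w}x{h} not divisible by {factor}")
    blocks = pixels.reshape(h // factor, factor, w // factor, factor, 3)
    return np.round(blocks.mean(axis=(1, 3))).astype(np.uint8)


def _tissue_mask(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.canvas
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.tissue_smoothness)
    mask = field_ >= np.quantile(field_, 1.0 - spec.tissue_coverage)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argsort(sizes)[::-1][: spec.tissue_blobs] + 1
    return np.isin(labels, keep)


def _place_nuclei(
    spec: SyntheticSlideSpec, tissue: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample nucleus centers: fully on tissue, non-clump members
    well separated, clump members in overlapping pairs (centers at 0.7 times
    the sum of radii)."""
    n = spec.nucleus_count
    if n == 0:
        return np.zeros((0, 2)), np.zeros(0)
    w, h = spec.canvas
    lo, hi = spec.nucleus_diameter_range
    dt = ndimage.distance_transform_edt(tissue)
    n_pairs = int(round(n * spec.clump_fraction / 2.0))
    placed_xy: list[tuple[float, float]] = []
    placed_d: list[float] = []

    def ok(x: float, y: float, d: float, partner_idx: int | None = None) -> bool:
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            return False
        if dt[yi, xi] < d / 2.0 + 1.0:  # whole disk on tissue
            return False
        for j, ((px, py), pd) in enumerate(zip(placed_xy, placed_d)):
            if j == partner_idx:
                continue
            min_sep = (d + pd) / 2.0 + 4.0
            if (x - px) ** 2 + (y - py) ** 2 < min_sep**2:
                return False
        return True

    max_attempts = 400 * n + 4000
    attempts = 0

    def draw_center() -> tuple[float, float]:
        return rng.uniform(0, w), rng.uniform(0, h)

    for _ in range(n_pairs):
        # clump members share a diameter: at 0.7x the sum of radii a much
        # smaller nucleus would sit inside the larger disk and the pair would
        # not be bimodal in intensity at all
        d1 = d2 = rng.uniform(lo, hi)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    "could not place all nuclei; lower nucleus_count or enlarge canvas"
                )
            x1, y1 = draw_center()
            if not ok(x1, y1, d1):
                continue
            theta = rng.uniform(0, 2 * np.pi)
            sep = 0.7 * (d1 + d2) / 2.0
            x2, y2 = x1 + sep * np.cos(theta), y1 + sep * np.sin(theta)
            placed_xy.append((x1, y1))
            placed_d.append(d1)
            if ok(x2, y2, d2, partner_idx=len(placed_xy) - 1):
                placed_xy.append((x2, y2))
                placed_d.append(d2)
                break
            placed_xy.pop()
            placed_d.pop()

    while len(placed_xy) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                "could not place all nuclei; lower nucleus_count or enlarge canvas"
            )
        d = rng.uniform(lo, hi)
        x, y = draw_center()
        if ok(x, y, d):
            placed_xy.append((x, y))
            placed_d.append(d)

    return np.array(placed_xy, dtype=np.float64), np.array(placed_d, dtype=np.float64)


def _dab_field(
    canvas: tuple[int, int], xy: np.ndarray, diam: np.ndarray, dab_od: float
) -> np.ndarray:
    """Max-composite of radially profiled nucleus disks, in OD units."""
    w, h = canvas
    out = np.zeros((h, w), dtype=np.float64)
    for (x, y), d in zip(xy, diam):
        r = d / 2.0
        x0, x1 = max(0, int(np.floor(x - r - 1))), min(w, int(np.ceil(x + r + 2)))
        y0, y1 = max(0, int(np.floor(y - r - 1))), min(h, int(np.ceil(y + r + 2)))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rho2 = ((xx - x) ** 2 + (yy - y) ** 2) / r**2
        inside = rho2 <= 1.0
        profile = dab_od * (1.0 + NUCLEUS_CENTER_BUMP * (1.0 - rho2))
        patch = np.where(inside, profile, 0.0)
        np.maximum(out[y0:y1, x0:x1], patch, out=out[y0:y1, x0:x1])
    return out


def _render_clean(spec: SyntheticSlideSpec, basis: StainBasis):
    """Deterministic noiseless float image plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec, rng)
    xy, diam = _place_nuclei(spec, tissue, rng)
    w, h = spec.canvas
    c_hema = ndimage.gaussian_filter(tissue.astype(np.float64), 1.0) * spec.hematoxylin_od
    c_dab = _dab_field(spec.canvas, xy, diam, spec.dab_od)
    v_dab = basis.vector("dab")
    v_hema = basis.vector("hematoxylin")
    od = c_dab[..., None] * v_dab + c_hema[..., None] * v_hema
    i0 = np.asarray(basis.background_intensity, dtype=np.float64)
    image = i0 * np.power(10.0, -od)
    truth = GroundTruth(
        positions=xy, diameters=diam, tissue_area=int(tissue.sum()), spec=spec
    )
    return image, truth


def _finish(
    image: np.ndarray,
    spec: SyntheticSlideSpec,
    noise_sigma: float,
    noise_rng: np.random.Generator | None,
    illumination_scale: float = 1.0,
) -> PyramidSlide:
    """Apply illumination scale + sensor noise, quantize, build the pyramid."""
    out = image * illumination_scale
    if noise_sigma > 0 and noise_rng is not None:
        out = out + noise_rng.normal(0.0, noise_sigma, size=out.shape)
    top = np.clip(np.round(out), 0, 255).astype(np.uint8)
    layers = [
        Layer(top, magnification=spec.top_magnification),
        Layer(block_mean_downsample(top, 2), magnification=spec.top_magnification / 2),
        Layer(block_mean_downsample(top, 32), magnification=spec.top_magnification / 32),
    ]
    meta = SlideMetadata(
        pixels_per_micrometer=spec.pixels_per_micrometer, layer_count=len(layers)
    )
    return PyramidSlide(layers=layers, metadata=meta, source_name=f"synthetic-{spec.seed}")


def render_slide(
    spec: SyntheticSlideSpec, basis: StainBasis | None = None
) -> tuple[PyramidSlide, GroundTruth]:
    """Render one synthetic pyramid slide with its ground truth.

    Deterministic for a fixed spec (seed included). Artifacts listed in the
    spec are applied after staining via :func:`add_artifacts`.
    """
    basis = basis or StainBasis()
    image, truth = _render_clean(spec, basis)
    noise_rng = np.random.default_rng(spec.seed + 1) if spec.noise_sigma > 0 else None
    slide = _finish(image, spec, spec.noise_sigma, noise_rng)
    if spec.artifacts:
        slide, truth = add_artifacts(slide, truth, set(spec.artifacts))
    return slide, truth


def _rebuild_pyramid(top: np.ndarray, slide: PyramidSlide) -> PyramidSlide:
    layers = [Layer(top, magnification=slide.layers[0].magnification)]
    for lay in slide.layers[1:]:
        factor = round(top.shape[1] / lay.width)
        layers.append(Layer(block_mean_downsample(top, factor), magnification=lay.magnification))
    return PyramidSlide(layers=layers, metadata=slide.metadata, source_name=slide.source_name)


def _off_tissue_spot(truth: GroundTruth, shape: tuple[int, int]) -> tuple[int, int, float]:
    """Pick the point farthest from tissue and nuclei; return (x, y, clearance)."""
    spec = truth.spec
    assert spec is not None
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec, rng)  # same field as the render (same rng stream head)
    occupied = tissue.copy()
    h, w = shape
    for (x, y), d in zip(truth.positions, truth.diameters):
        yy, xx = int(round(y)), int(round(x))
        occupied[max(0, yy - 1) : yy + 2, max(0, xx - 1) : xx + 2] = True
    dt = ndimage.distance_transform_edt(~occupied)
    iy, ix = np.unravel_index(np.argmax(dt), dt.shape)
    return int(ix), int(iy), float(dt[iy, ix])


def add_artifacts(
    slide: PyramidSlide, truth: GroundTruth, artifacts: set[str]
) -> tuple[PyramidSlide, GroundTruth]:
    """Stamp scanning artifacts onto a rendered slide; truth stays invariant.

    air_bubble: a broken dark ring off-tissue (stain pooled at the bubble
    rim), the classic unmasked-artifact failure mode. coverslip_shadow: a
    darkened band along one edge. pen_mark: a saturated marker stroke
    off-tissue. Regions are recorded in the ground truth so tests (and mask
    editors) can hide them.
    """
    if not artifacts:
        raise ValueError("artifact set must be non-empty")
    bad = set(artifacts) - set(ARTIFACT_KINDS)
    if bad:
        raise ValueError(f"unknown artifacts: {sorted(bad)}")
    top = slide.layers[0].pixels.astype(np.float64)
    h, w = top.shape[:2]
    regions = dict(truth.artifact_regions)
    basis = StainBasis()

    if "air_bubble" in artifacts:
        cx, cy, clearance = _off_tissue_spot(truth, (h, w))
        # keep the recorded region (ring + padding) clear of tissue so that
        # masking the box can never clip a real nucleus
        radius = max(20.0, min(min(w, h) / 8.0, clearance - 16.0))
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ring = (np.abs(rr - radius) <= 4.0)
        # break the rim into arcs so the bubble reads as nucleus-sized blobs
        ang = np.arctan2(yy - cy, xx - cx)
        ring &= (np.floor((ang + np.pi) / (np.pi / 10)) % 2) == 0
        od = 1.0 * basis.vector("dab") + 0.4 * basis.vector("hematoxylin")
        rim = 255.0 * np.power(10.0, -od)
        top[ring] = rim
        pad = int(radius + 8)
        regions["air_bubble"] = (
            max(0, cx - pad), max(0, cy - pad), min(w, cx + pad), min(h, cy + pad)
        )

    if "coverslip_shadow" in artifacts:
        band = max(8, w // 12)
        top[:, :band] *= 0.85
        regions["coverslip_shadow"] = (0, 0, band, h)

    if "pen_mark" in artifacts:
        band = max(4, h // 60)
        y0 = h - 3 * band
        top[y0 : y0 + band, w // 8 : w - w // 8] = (30.0, 120.0, 60.0)
        regions["pen_mark"] = (w // 8, y0, w - w // 8, y0 + band)

    new_top = np.clip(np.round(top), 0, 255).astype(np.uint8)
    new_slide = _rebuild_pyramid(new_top, slide)
    new_truth = GroundTruth(
        positions=truth.positions,
        diameters=truth.diameters,
        tissue_area=truth.tissue_area,
        artifact_regions=regions,
        spec=truth.spec,
    )
    return new_slide, new_truth


def render_replicate(
    slide_spec: SyntheticSlideSpec,
    rescan_noise_sigma: float,
    rescan_seed: int,
    illumination_scaling: bool = True,
    basis: StainBasis | None = None,
) -> PyramidSlide:
    """Re-scan the same slide: identical geometry/truth, fresh sensor noise.

    Emulates run-to-run scanner variation with independent Gaussian noise and
    a small global illumination scale drawn uniformly from +/-1%.
    """
    if rescan_noise_sigma < 0:
        raise ValueError("rescan_noise_sigma must be >= 0")
    basis = basis or StainBasis()
    image, truth = _render_clean(slide_spec, basis)
    rng = np.random.default_rng(rescan_seed)
    scale = 1.0 + rng.uniform(-0.01, 0.01) if illumination_scaling else 1.0
    slide = _finish(image, slide_spec, rescan_noise_sigma, rng, illumination_scale=scale)
    if slide_spec.artifacts:
        slide, _ = add_artifacts(slide, truth, set(slide_spec.artifacts))
    return slide
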