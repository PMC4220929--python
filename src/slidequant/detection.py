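"""DAB-positive nucleus detection on slide tiles.

Reimplements, natively, the image-cytometry pipeline used for CD3/DAB
quantification: grayscale tissue segmentation, color deconvolution of the
brown DAB chromogen from the hematoxylin counterstain in optical-density
space, global three-class Otsu thresholding (entropy criterion, middle class
to foreground, correction factor and bounds), primary-object identification
with a diameter gate and intensity-based declumping of touching nuclei, and
area/count measurements with QC outline overlays.

Stains attenuate transmitted light multiplicatively (Beer–Lambert), so they
add linearly in optical density OD = -log10(I/I0). A pixel's OD vector is the
sum of per-stain unit "color vectors" scaled by local stain amounts; inverting
that linear model (least squares, non-negativity clip) yields one grayscale
concentration channel per stain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.segmentation import find_boundaries, watershed

__all__ = [
    "StainBasis",
    "ConcentrationImage",
    "ThresholdSpec",
    "ObjectSet",
    "TileMeasurement",
    "DegenerateInputError",
    "rgb_to_od",
    "unmix",
    "otsu_three_class",
    "resolve_threshold",
    "identify_primary_objects",
    "declump_by_intensity",
    "segment_tissue",
    "measure_tile",
    "render_overlay",
]

# Published optical-density color vectors for hematoxylin and DAB
# (Ruifrok & Johnston color-deconvolution values), unit-normalized below.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.268, 0.570, 0.776)

#: Concentration normalization: OD amounts are divided by this value to map
#: stain concentrations onto [0, 1], where the absolute threshold bounds
#: 0.5 / 1.0 live. Configurable; 1.5 OD makes those bounds meaningful for
#: typical chromogen densities.
DEFAULT_C_MAX = 1.5

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


class DegenerateInputError(ValueError):
    """Raised when an image has too little value diversity to threshold."""


@dataclass
class StainBasis:
    """Unit stain vectors in OD space plus the background intensity I0."""

    names: tuple[str, ...] = ("dab", "hematoxylin")
    vectors: np.ndarray = field(
        default_factory=lambda: np.array([DAB_OD, HEMATOXYLIN_OD], dtype=np.float64)
    )
    background_intensity: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("stain vectors must be (n_stains, 3)")
        if len(self.names) != self.vectors.shape[0]:
            raise ValueError("one name per stain vector required")
        if np.any(self.vectors < 0):
            raise ValueError("stain vectors must be non-negative")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        self.vectors = self.vectors / norms[:, None]
        if np.linalg.matrix_rank(self.vectors) < self.vectors.shape[0]:
            raise ValueError("stain vectors must be linearly independent")

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[self.names.index(name)]


@dataclass
class ConcentrationImage:
    """One stain's per-pixel amount, rescaled to [0, 1] by ``c_max``."""

    stain: str
    values: np.ndarray  # (H, W) float in [0, 1]
    c_max: float


@dataclass
class ThresholdSpec:
    """How a raw automatic threshold becomes the operative cutoff.

    Mirrors the thresholding controls of the original pipeline: three-class
    Otsu with the entropy criterion, middle intensity class assigned to the
    foreground, a multiplicative correction factor, and absolute clamping
    bounds on the [0, 1] concentration scale.
    """

    method: str = "otsu3_entropy"  # otsu3_entropy | otsu3_variance | absolute
    correction_factor: float = 1.3
    lower_bound: float = 0.5
    upper_bound: float = 1.0
    middle_class_to: str = "foreground"  # foreground | background
    absolute_value: float | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must be <= upper_bound")
        if self.method not in ("otsu3_entropy", "otsu3_variance", "absolute"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.middle_class_to not in ("foreground", "background"):
            raise ValueError("middle_class_to must be 'foreground' or 'background'")


@dataclass
class ObjectSet:
    """Labeled objects: integer raster (0 = background) plus a feature table."""

    label_raster: np.ndarray
    table: pd.DataFrame  # id, area, centroid_r, centroid_c, equivalent_diameter

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def total_area(self) -> int:
        return int(self.table["area"].sum()) if len(self.table) else 0


@dataclass
class TileMeasurement:
    tile_id: str
    tissue_area: int
    dab_object_count: int
    dab_area: int


def _object_set_from_labels(labels: np.ndarray) -> ObjectSet:
    n = int(labels.max())
    if n == 0:
        table = pd.DataFrame(
            columns=["id", "area", "centroid_r", "centroid_c", "equivalent_diameter"]
        )
        return ObjectSet(labels.astype(np.int32), table)
    ids = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64), labels, ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, ids)
    cr, cc = zip(*centroids)
    table = pd.DataFrame(
        {
            "id": ids,
            "area": areas.astype(np.int64),
            "centroid_r": cr,
            "centroid_c": cc,
            "equivalent_diameter": 2.0 * np.sqrt(areas / np.pi),
        }
    )
    return ObjectSet(labels.astype(np.int32), table)


def _filter_objects(objs: ObjectSet, keep_ids: np.ndarray) -> ObjectSet:
    """Keep the given object ids and renumber labels contiguously from 1."""
    keep_ids = np.asarray(sorted(keep_ids), dtype=np.intp)
    n_old = int(objs.label_raster.max())
    remap = np.zeros(n_old + 1, dtype=np.int32)
    if len(keep_ids):
        remap[keep_ids] = np.arange(1, len(keep_ids) + 1)
    labels = remap[objs.label_raster]
    table = objs.table[objs.table["id"].isin(keep_ids)].copy()
    table["id"] = np.arange(1, len(table) + 1)
    return ObjectSet(labels, table.reset_index(drop=True))


def rgb_to_od(
    pixels: np.ndarray, background_intensity=(255.0, 255.0, 255.0)
) -> np.ndarray:
    """Convert 8-bit RGB to optical density: OD_c = -log10((v+1)/(I0+1)), >= 0.

    The +1 regularization keeps zero-valued pixels finite; pixels brighter
    than the background clip to zero density.
    """
    i0 = np.asarray(background_intensity, dtype=np.float64)
    if np.any(i0 <= 0):
        raise ValueError("background intensity must be positive per channel")
    v = np.asarray(pixels, dtype=np.float64)
    od = -np.log10((v + 1.0) / (i0 + 1.0))
    return np.maximum(od, 0.0)


def unmix(od: np.ndarray, basis: StainBasis, c_max: float = DEFAULT_C_MAX):
    """Least-squares projection of per-pixel OD onto the stain vectors.

    Returns a dict of stain name -> :class:`ConcentrationImage`. Negative
    amounts (noise outside the stain cone) clip to 0; amounts are divided by
    ``c_max`` and clipped to 1.
    """
    M = basis.vectors  # (S, 3); rank-checked in StainBasis
    pinv = np.linalg.pinv(M.T)  # (S, 3): c = pinv @ od
    flat = od.reshape(-1, 3)
    conc = flat @ pinv.T  # (N, S)
    conc = np.clip(conc, 0.0, None) / c_max
    conc = np.clip(conc, 0.0, 1.0)
    out = {}
    for k, name in enumerate(basis.names):
        out[name] = ConcentrationImage(
            stain=name, values=conc[:, k].reshape(od.shape[:2]), c_max=c_max
        )
    return out


def _class_term(omega: np.ndarray) -> np.ndarray:
    # omega*log(omega) with the 0*log(0) = 0 convention
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = omega[pos] * np.log(omega[pos])
    return out


def otsu_three_class(
    values: np.ndarray, criterion: str = "entropy", bins: int = 256
) -> tuple[float, float]:
    """Global three-class Otsu thresholds (t_low, t_high) on the [0, 1] scale.

    Exhaustive search over all ordered bin-boundary pairs, minimizing either
    the weighted sum of within-class entropies (class histograms normalized to
    1) or the weighted intra-class variance. For the entropy criterion the
    within-class sum Σ p·log p telescopes to the constant total entropy, so
    the search reduces exactly to minimizing Σ_k ω_k·log ω_k.
    """
    if bins < 16:
        raise ValueError("bins must be >= 16")
    if criterion not in ("entropy", "variance"):
        raise ValueError(f"unknown criterion {criterion!r}")
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < 3:
        raise DegenerateInputError(
            "need at least 3 distinct values for three-class thresholding"
        )
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    cumw = np.concatenate([[0.0], np.cumsum(p)])  # cumw[k] = mass of bins < k
    a = np.arange(1, bins - 1)  # low boundary: class 1 = bins [0, a)
    b = np.arange(2, bins)      # high boundary: class 2 = bins [a, b)

    if criterion == "entropy":
        w1 = _class_term(cumw[a])[:, None]
        w3 = _class_term(1.0 - cumw[b])[None, :]
        mid = cumw[b][None, :] - cumw[a][:, None]
        w2 = _class_term(np.clip(mid, 0.0, None))
        crit = w1 + w2 + w3
    else:
        centers = (edges[:-1] + edges[1:]) / 2.0
        cm1 = np.concatenate([[0.0], np.cumsum(p * centers)])
        cm2 = np.concatenate([[0.0], np.cumsum(p * centers**2)])

        def intra(w, m1, m2):
            # w*sigma^2 = E[x^2] - m1^2/w over the class, 0 for empty classes
            out = np.zeros_like(w)
            pos = w > 1e-300
            out[pos] = m2[pos] - m1[pos] ** 2 / w[pos]
            return out

        v1 = intra(cumw[a], cm1[a], cm2[a])[:, None]
        v3 = intra(1.0 - cumw[b], cm1[-1] - cm1[b], cm2[-1] - cm2[b])[None, :]
        wmid = cumw[b][None, :] - cumw[a][:, None]
        v2 = intra(
            np.clip(wmid, 0.0, None),
            cm1[b][None, :] - cm1[a][:, None],
            cm2[b][None, :] - cm2[a][:, None],
        )
        crit = v1 + v2 + v3

    invalid = b[None, :] <= a[:, None]
    crit = np.where(invalid, np.inf, crit)
    ia, ib = np.unravel_index(np.argmin(crit), crit.shape)
    return float(edges[a[ia]]), float(edges[b[ib]])


def resolve_threshold(spec: ThresholdSpec, raw: tuple[float, float]) -> float:
    """Turn raw (t_low, t_high) into the operative scalar threshold.

    With the middle class assigned to the foreground the operative raw
    threshold is t_low; it is scaled by the correction factor and clamped to
    the absolute bounds.
    """
    t_low, t_high = raw
    t = t_low if spec.middle_class_to == "foreground" else t_high
    return float(np.clip(t * spec.correction_factor, spec.lower_bound, spec.upper_bound))


def declump_by_intensity(
    foreground: np.ndarray, intensity: np.ndarray, suppression_radius: int = 4
) -> ObjectSet:
    """Split touching foreground clumps using intensity peaks and watershed.

    Seeds are local maxima of the Gaussian-smoothed intensity (sigma =
    suppression_radius/2) separated by at least ``suppression_radius``;
    connected regions without a detected peak are seeded at their intensity
    maximum so no foreground is lost. A watershed on the negated intensity,
    constrained to the foreground, assigns every foreground pixel to exactly
    one object.
    """
    if suppression_radius < 1:
        raise ValueError("suppression_radius must be >= 1")
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        return _object_set_from_labels(np.zeros(fg.shape, dtype=np.int32))
    smoothed = ndimage.gaussian_filter(
        np.asarray(intensity, dtype=np.float64), sigma=suppression_radius / 2.0
    )
    comp_labels, n_comp = ndimage.label(fg, structure=_EIGHT)
    # local maxima: pixels equal to the running maximum over the suppression
    # window; a connected plateau of maxima is one seed, not many, so large
    # uniform blobs are not shattered into spurious objects
    window = 2 * suppression_radius + 1
    maxfilt = ndimage.maximum_filter(smoothed, size=window, mode="nearest")
    peak_mask = (smoothed >= maxfilt) & fg
    peak_labels, n_peaks = ndimage.label(peak_mask, structure=_EIGHT)
    markers = np.zeros(fg.shape, dtype=np.int32)
    seeded = set()
    if n_peaks:
        # deterministic representative: first raster-order pixel per plateau
        flat_idx = np.full(n_peaks + 1, -1, dtype=np.int64)
        order = np.flatnonzero(peak_labels.ravel())
        lab_flat = peak_labels.ravel()[order]
        first = np.unique(lab_flat, return_index=True)[1]
        flat_idx[lab_flat[first]] = order[first]
    for k in range(1, n_peaks + 1):
        r, c = np.unravel_index(flat_idx[k], fg.shape)
        markers[r, c] = k
        seeded.add(int(comp_labels[r, c]))
    next_id = n_peaks + 1
    missing = set(range(1, n_comp + 1)) - seeded
    if missing:
        masked = np.where(fg, smoothed, -np.inf)
        for comp in sorted(missing):
            inside = comp_labels == comp
            idx = np.unravel_index(np.argmax(np.where(inside, masked, -np.inf)), fg.shape)
            markers[idx] = next_id
            next_id += 1
    labels = watershed(-smoothed, markers=markers, mask=fg, connectivity=2)
    # renumber contiguously in raster order of first occurrence
    return _object_set_from_labels(_contiguous(labels))


def _contiguous(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]


def identify_primary_objects(
    channel,
    threshold: float,
    min_diameter: float = 8.0,
    max_diameter: float = 26.0,
    declump: bool = True,
    suppression_radius: int | None = None,
) -> ObjectSet:
    """Threshold a concentration channel and label objects within a size gate.

    Foreground is ``channel >= threshold`` (8-connected components). With
    ``declump`` enabled, clumps are split by intensity before gating. Objects
    whose equivalent diameter (2*sqrt(area/pi)) falls outside
    [min_diameter, max_diameter] are discarded entirely and the remaining
    labels renumbered contiguously.
    """
    if not min_diameter < max_diameter:
        raise ValueError("min_diameter must be < max_diameter")
    values = channel.values if isinstance(channel, ConcentrationImage) else np.asarray(channel)
    fg = values >= threshold
    if declump:
        radius = suppression_radius or max(1, int(round(min_diameter / 2.0)))
        objs = declump_by_intensity(fg, values, suppression_radius=radius)
    else:
        labels, _ = ndimage.label(fg, structure=_EIGHT)
        objs = _object_set_from_labels(labels)
    if objs.count == 0:
        return objs
    t = objs.table
    ok = t.loc[
        (t["equivalent_diameter"] >= min_diameter)
        & (t["equivalent_diameter"] <= max_diameter),
        "id",
    ].to_numpy()
    return _filter_objects(objs, ok)


def segment_tissue(
    pixels: np.ndarray,
    smooth_sigma: float = 5.0,
    absolute_threshold: float = 0.03,
    min_diameter: float = 40.0,
) -> ObjectSet:
    """Segment tissue from an RGB tile.

    The tile is converted to grayscale luminance in [0, 1], smoothed with a
    Gaussian (default sigma 5, i.e. a ~20 px blur diameter mapped as
    diameter/4), inverted, and thresholded at an absolute 0.03. Components
    smaller than the 40 px gate (read as minimum equivalent diameter) are
    removed.
    """
    gray = rgb2gray(np.asarray(pixels))
    smoothed = ndimage.gaussian_filter(gray, sigma=smooth_sigma) if smooth_sigma > 0 else gray
    inverted = 1.0 - smoothed
    fg = inverted >= absolute_threshold
    labels, _ = ndimage.label(fg, structure=_EIGHT)
    objs = _object_set_from_labels(labels)
    if objs.count == 0:
        return objs
    ok = objs.table.loc[objs.table["equivalent_diameter"] >= min_diameter, "id"].to_numpy()
    return _filter_objects(objs, ok)


def measure_tile(
    tile,
    basis: StainBasis | None = None,
    dab_threshold_spec: ThresholdSpec | None = None,
    min_diameter: float = 8.0,
    max_diameter: float = 26.0,
    c_max: float = DEFAULT_C_MAX,
    restrict_to_tissue: bool = True,
    tissue_kwargs: dict | None = None,
):
    """Measure one tile: tissue area, DAB nucleus count and DAB area.

    ``tile`` may be a :class:`slidequant.tiling.Tile` or a bare RGB array.
    Returns (TileMeasurement, tissue ObjectSet, dab ObjectSet). DAB objects
    that do not touch the tissue foreground are discarded (counts are reported
    per tissue area); objects touching the tile border are kept, since tiles
    do not overlap and border discards would systematically undercount seams.
    """
    if basis is None:
        basis = StainBasis()
    if dab_threshold_spec is None:
        dab_threshold_spec = ThresholdSpec()
    pixels = getattr(tile, "pixels", tile)
    tile_id = getattr(getattr(tile, "entry", None), "filename", "tile")

    tissue = segment_tissue(pixels, **(tissue_kwargs or {}))

    od = rgb_to_od(pixels, basis.background_intensity)
    dab = unmix(od, basis, c_max=c_max)["dab"]
    if dab_threshold_spec.method == "absolute":
        threshold = float(dab_threshold_spec.absolute_value)
    else:
        criterion = "entropy" if dab_threshold_spec.method == "otsu3_entropy" else "variance"
        try:
            raw = otsu_three_class(dab.values, criterion=criterion)
            threshold = resolve_threshold(dab_threshold_spec, raw)
        except DegenerateInputError:
            # near-constant channel (blank tile): clamp floor is the only
            # defensible cutoff, and it yields zero foreground on blanks
            threshold = max(dab_threshold_spec.lower_bound, 1e-6)

    objs = identify_primary_objects(
        dab, threshold, min_diameter=min_diameter, max_diameter=max_diameter, declump=True
    )
    if restrict_to_tissue and objs.count > 0:
        on_tissue = tissue.label_raster > 0
        ids = np.unique(objs.label_raster[(objs.label_raster > 0) & on_tissue])
        objs = _filter_objects(objs, ids)
    meas = TileMeasurement(
        tile_id=str(tile_id),
        tissue_area=tissue.total_area,
        dab_object_count=objs.count,
        dab_area=objs.total_area,
    )
    return meas, tissue, objs


def render_overlay(tile, tissue: ObjectSet, dab: ObjectSet) -> np.ndarray:
    """QC overlay: tissue outlined blue, DAB nuclei green (drawn on top)."""
    pixels = getattr(tile, "pixels", tile)
    out = np.asarray(pixels).copy()
    if tissue.count > 0:
        edges = find_boundaries(tissue.label_raster, mode="inner")
        out[edges] = (0, 0, 255)
    if dab.count > 0:
        edges = find_boundaries(dab.label_raster, mode="inner")
        out[edges] = (0, 255, 0)
    return out
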