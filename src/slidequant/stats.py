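"""Per-slide aggregation and replicate-agreement statistics.

Tile measurements are combined per slide into total tissue area, total
DAB-positive nucleus count and a density (nuclei per tissue area, computed
from the totals — not the mean of per-tile ratios). Agreement between two
pipeline runs of the same slides is quantified by the two-way mixed-effects
single-measures intraclass correlation, ICC(3,1), and by Bland–Altman
limits of agreement on log-transformed densities, log(0.0001 + x), with
pairs differing by more than 0.50 on that scale flagged for manual review
(in practice such outliers trace back to mask discrepancies).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import TileMeasurement

__all__ = [
    "SlideMeasurement",
    "ReplicatePair",
    "ICCResult",
    "BlandAltmanResult",
    "combine_slide",
    "transform_density",
    "icc_two_way_mixed_single",
    "bland_altman",
    "plot_bland_altman",
]

#: Offset inside the log transform; keeps zero-count slides finite and
#: damps log-scale noise at very low densities.
LOG_OFFSET = 1e-4

#: Review threshold on the absolute log-scale difference between runs.
OUTLIER_DIFF = 0.50


@dataclass
class SlideMeasurement:
    slide_id: str
    total_tissue_area: float
    total_dab_count: int
    density: float | None  # None when tissue area is 0 (flagged undefined)

    @property
    def density_defined(self) -> bool:
        return self.density is not None


@dataclass
class ReplicatePair:
    slide_id: str
    run1_density: float
    run2_density: float


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_error: float
    n_subjects: int
    k_raters: int


@dataclass
class BlandAltmanResult:
    means: np.ndarray
    differences: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    outliers: list[str] = field(default_factory=list)


def combine_slide(measurements: list[TileMeasurement], slide_id: str = "") -> SlideMeasurement:
    """Combine per-tile measurements into one per-slide record.

    Totals are sums over tiles; the density is total count over total tissue
    area (a tissue-area-weighted quantity), not the mean of per-tile ratios.
    """
    if not measurements:
        raise ValueError("cannot combine an empty list of tile measurements")
    area = float(sum(m.tissue_area for m in measurements))
    count = int(sum(m.dab_object_count for m in measurements))
    density = count / area if area > 0 else None
    return SlideMeasurement(
        slide_id=slide_id,
        total_tissue_area=area,
        total_dab_count=count,
        density=density,
    )


def transform_density(x: float) -> float:
    """Log transform of a density: ln(0.0001 + x). Requires x >= 0."""
    if x < 0:
        raise ValueError(f"density must be non-negative, got {x}")
    return math.log(LOG_OFFSET + x)


def _pairs_matrix(pairs: list[ReplicatePair]) -> np.ndarray:
    return np.array([[p.run1_density, p.run2_density] for p in pairs], dtype=np.float64)


def icc_two_way_mixed_single(pairs: list[ReplicatePair] | np.ndarray) -> ICCResult:
    """ICC(3,1): two-way mixed-effects, consistency, single measures.

    From the two-way ANOVA decomposition of the n x k matrix (subjects x
    runs): ICC = (MS_rows - MS_error) / (MS_rows + (k-1) * MS_error), where
    MS_error is the residual mean square after removing subject and run
    effects. Run (column) offsets therefore do not penalize agreement.
    """
    data = pairs if isinstance(pairs, np.ndarray) else _pairs_matrix(pairs)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 raters")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subject rows, got {n}")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite values are not supported")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    icc = 1.0 if denom == 0 else (ms_rows - ms_err) / denom
    return ICCResult(
        icc=float(icc), ms_rows=float(ms_rows), ms_error=float(ms_err),
        n_subjects=n, k_raters=k,
    )


def icc_two_way_mixed_single_absolute(pairs: list[ReplicatePair] | np.ndarray) -> ICCResult:
    """Absolute-agreement variant ICC(A,1): run offsets count against agreement."""
    data = pairs if isinstance(pairs, np.ndarray) else _pairs_matrix(pairs)
    base = icc_two_way_mixed_single(data)
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    grand = data.mean()
    col_means = data.mean(axis=0)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    num = base.ms_rows - base.ms_error
    denom = base.ms_rows + (k - 1) * base.ms_error + (k / n) * (ms_cols - base.ms_error)
    icc = 1.0 if denom == 0 else num / denom
    return ICCResult(
        icc=float(icc), ms_rows=base.ms_rows, ms_error=base.ms_error,
        n_subjects=n, k_raters=k,
    )


def bland_altman(pairs: list[ReplicatePair], transform: bool = True) -> BlandAltmanResult:
    """Bland–Altman agreement of two runs, optionally on the log scale.

    Bias is the mean difference run1 - run2; the 95% limits of agreement are
    bias +/- 1.96 * sd(difference). Pairs with |difference| > 0.50 on the
    analysis scale are listed as outliers for manual mask review.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    if transform:
        a = np.array([transform_density(p.run1_density) for p in pairs])
        b = np.array([transform_density(p.run2_density) for p in pairs])
    else:
        a = np.array([p.run1_density for p in pairs], dtype=np.float64)
        b = np.array([p.run2_density for p in pairs], dtype=np.float64)
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    outliers = [p.slide_id for p, d in zip(pairs, diff) if abs(d) > OUTLIER_DIFF]
    return BlandAltmanResult(
        means=mean, differences=diff, bias=bias,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, outliers=outliers,
    )


def plot_bland_altman(result: BlandAltmanResult, path: str | os.PathLike) -> Path:
    """Mean-vs-difference plot with bias and limit-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(result.means, result.differences, s=18, alpha=0.8)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias {result.bias:.3f}")
    for y, name in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="gray", lw=1, ls="--", label=f"{name} {y:.3f}")
    ax.set_xlabel("mean of runs, log(0.0001 + density)")
    ax.set_ylabel("difference run1 - run2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def agreement_report(
    pairs: list[ReplicatePair], out_dir: str | os.PathLike, transform: bool = True
) -> dict:
    """Write agreement.csv, icc.json and the Bland–Altman plot for run pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ba = bland_altman(pairs, transform=transform)
    t = [transform_density(p.run1_density) for p in pairs]
    u = [transform_density(p.run2_density) for p in pairs]
    icc = icc_two_way_mixed_single(np.column_stack([t, u]) if transform else _pairs_matrix(pairs))
    df = pd.DataFrame(
        {
            "slide_id": [p.slide_id for p in pairs],
            "run1_density": [p.run1_density for p in pairs],
            "run2_density": [p.run2_density for p in pairs],
            "run1_transformed": t,
            "run2_transformed": u,
            "difference": ba.differences,
            "outlier": [p.slide_id in ba.outliers for p in pairs],
        }
    )
    df.to_csv(out_dir / "agreement.csv", index=False)
    payload = {
        "icc": icc.icc,
        "n_subjects": icc.n_subjects,
        "k_raters": icc.k_raters,
        "bias": ba.bias,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "outliers": ba.outliers,
    }
    (out_dir / "icc.json").write_text(json.dumps(payload, indent=2))
    plot_bland_altman(ba, out_dir / "bland_altman.png")
    return payload
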