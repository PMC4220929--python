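"""The four-step workflow: acquisition -> preparation -> tiles -> analysis.

``run_pipeline`` drives one slide end to end: read the pyramid, build the
staging directory (thumbnail, mask), tile the analysis layer under the
upscaled mask, measure every included tile, and combine the tile rows into a
per-slide summary. ``run_batch`` runs many slides independently (serial or
parallel, with identical outputs either way); one failing slide is logged and
skipped, never fatal to the batch.
"""

from __future__ import annotations

import json
import os
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from . import detection, masking, slide_io, stats, tiling
from .config import RunConfig

__all__ = ["SlideResult", "measure_slide", "run_pipeline", "run_batch"]

MEASUREMENT_COLUMNS = ["tile", "tissue_area_px", "dab_count", "dab_area_px"]


@dataclass
class SlideResult:
    slide_id: str
    status: str  # "ok" | "failed"
    measurement: stats.SlideMeasurement | None = None
    staging_dir: Path | None = None
    error: str | None = None
    tile_rows: list[tuple] = field(default_factory=list)


def measure_slide(
    slide: slide_io.PyramidSlide,
    config: RunConfig,
    mask: masking.Mask | None = None,
    slide_id: str = "",
) -> tuple[stats.SlideMeasurement, list[detection.TileMeasurement], tiling.TilePlan]:
    """Mask -> tile -> detect -> combine, entirely in memory.

    When ``mask`` is None it is generated from the configured miniature
    layer. Returns the combined slide measurement, the per-tile rows and the
    tile plan (excluded tiles included, for bookkeeping).
    """
    analysis = slide_io.select_layer(slide, config.analysis_magnification)
    if mask is None:
        mini = slide_io.select_layer(slide, config.mask_magnification)
        mask = masking.generate_mask(
            mini, blur_sigma=config.blur_sigma, fuzz=config.fuzz,
            min_region=config.min_region,
        )
    plan = tiling.plan_tiles(analysis, mask, tile_size=config.tile_size,
                             min_keep=config.min_keep)
    rows: list[detection.TileMeasurement] = []
    for tile in tiling.iter_tiles(analysis, plan, mask):
        meas, _, _ = detection.measure_tile(
            tile,
            dab_threshold_spec=config.threshold,
            min_diameter=config.min_diameter,
            max_diameter=config.max_diameter,
            c_max=config.c_max,
            restrict_to_tissue=config.restrict_to_tissue,
            tissue_kwargs={
                "smooth_sigma": config.tissue_smooth_sigma,
                "absolute_threshold": config.tissue_threshold,
                "min_diameter": config.tissue_min_diameter,
            },
        )
        rows.append(meas)
    if not rows:  # fully excluded slide still yields a (zero) record
        rows = [detection.TileMeasurement("none", 0, 0, 0)]
    combined = stats.combine_slide(rows, slide_id=slide_id)
    return combined, rows, plan


def run_pipeline(
    slide_path: str | os.PathLike,
    config: RunConfig | None = None,
    out_root: str | os.PathLike = ".",
    mask_path: str | os.PathLike | None = None,
) -> SlideResult:
    """Process one slide into its staging directory.

    Layout: ``<out_root>/<name>/`` holding thumbnail.png, mask.png, tiles/
    (lossless PNG + manifest.csv, when enabled), overlays/ (optional),
    measurements.csv and summary.json. An externally edited mask supplied via
    ``mask_path`` (or found as ``<name>.mask.png`` beside the slide) replaces
    the generated one.
    """
    config = config or RunConfig()
    slide_path = Path(slide_path)
    slide_id = slide_path.name.removesuffix(".tif").removesuffix(".tiff")
    staging = Path(out_root) / slide_id
    try:
        slide = slide_io.read_pyramid(
            slide_path, nominal_magnification=config.nominal_magnification
        )
        staging.mkdir(parents=True, exist_ok=True)
        thumb = slide_io.make_thumbnail(slide, max_edge=512)
        iio.imwrite(staging / "thumbnail.png", thumb.pixels)

        mini = slide_io.select_layer(slide, config.mask_magnification)
        sidecar = slide_path.with_name(slide_id + ".mask.png")
        chosen_mask_path = Path(mask_path) if mask_path else (
            sidecar if sidecar.exists() else None
        )
        if chosen_mask_path is not None:
            mask = masking.load_mask(
                chosen_mask_path, expected_shape=(mini.height, mini.width),
                source_magnification=mini.magnification,
            )
        else:
            mask = masking.generate_mask(
                mini, blur_sigma=config.blur_sigma, fuzz=config.fuzz,
                min_region=config.min_region,
            )
        masking.save_mask(mask, staging / "mask.png")

        analysis = slide_io.select_layer(slide, config.analysis_magnification)
        plan = tiling.plan_tiles(analysis, mask, tile_size=config.tile_size,
                                 min_keep=config.min_keep)
        if config.save_tiles:
            tiling.extract_tiles(analysis, plan, mask, staging / "tiles")

        rows = []
        overlays_dir = staging / "overlays"
        if config.save_overlays:
            overlays_dir.mkdir(exist_ok=True)
        for tile in tiling.iter_tiles(analysis, plan, mask):
            meas, tissue, dab = detection.measure_tile(
                tile,
                dab_threshold_spec=config.threshold,
                min_diameter=config.min_diameter,
                max_diameter=config.max_diameter,
                c_max=config.c_max,
                restrict_to_tissue=config.restrict_to_tissue,
                tissue_kwargs={
                    "smooth_sigma": config.tissue_smooth_sigma,
                    "absolute_threshold": config.tissue_threshold,
                    "min_diameter": config.tissue_min_diameter,
                },
            )
            rows.append(meas)
            if config.save_overlays:
                iio.imwrite(
                    overlays_dir / tile.entry.filename,
                    detection.render_overlay(tile, tissue, dab),
                )
        if not rows:
            rows = [detection.TileMeasurement("none", 0, 0, 0)]
        df = pd.DataFrame(
            [(m.tile_id, m.tissue_area, m.dab_object_count, m.dab_area) for m in rows],
            columns=MEASUREMENT_COLUMNS,
        )
        df.to_csv(staging / "measurements.csv", index=False)
        combined = stats.combine_slide(rows, slide_id=slide_id)
        summary = {
            "slide": slide_id,
            "total_tissue_area_px": combined.total_tissue_area,
            "total_dab_count": combined.total_dab_count,
            "density": combined.density,
            "log_density": (
                stats.transform_density(combined.density)
                if combined.density is not None else None
            ),
            "tiles_included": len(plan.included),
            "tiles_total": len(plan.entries),
        }
        (staging / "summary.json").write_text(json.dumps(summary, indent=2))
        return SlideResult(
            slide_id=slide_id, status="ok", measurement=combined, staging_dir=staging,
        )
    except Exception as exc:  # noqa: BLE001 - batch isolation boundary
        msg = f"{type(exc).__name__}: {exc}"
        try:
            staging.mkdir(parents=True, exist_ok=True)
            (staging / "error.log").write_text(msg + "\n" + traceback.format_exc())
        except OSError:
            pass
        return SlideResult(slide_id=slide_id, status="failed", error=msg, staging_dir=staging)


def _run_one(args) -> SlideResult:
    path, config, out_root = args
    return run_pipeline(path, config, out_root)


def run_batch(
    manifest: list[str | os.PathLike],
    config: RunConfig | None = None,
    out_root: str | os.PathLike = ".",
    workers: int = 1,
) -> list[SlideResult]:
    """Process slides independently; parallel results equal serial results.

    A failing slide is reported in its result (and error.log) while the rest
    of the batch proceeds.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    config = config or RunConfig()
    jobs = [(Path(p), config, Path(out_root)) for p in manifest]
    if workers == 1 or len(jobs) <= 1:
        return [_run_one(j) for j in jobs]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_run_one, jobs))
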