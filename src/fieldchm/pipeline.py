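"""End-to-end orchestration: clouds in, growth tables out.

``process_clouds`` is the in-memory pipeline (filter → rasterize → impute
→ ROI → segment → rectify → CHM → statistics → fits/RGR) shared by the
CLI, the examples and the test-bench.  ``run_pipeline`` wraps it with file
I/O driven by a single YAML config and writes a manifest of every
artifact produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chm as chm_mod
from . import geometry, growth, raster

log = logging.getLogger("fieldchm")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "process_clouds",
    "run_pipeline",
    "load_config",
    "validate_against_reference",
    "rectify_blocks",
]


@dataclass
class RunConfig:
    """One source of truth for a pipeline run; every stage default is
    overridable here.  ``cloud_paths`` and ``times`` are parallel lists,
    times in days since the first flight."""

    cloud_paths: list[str]
    times: list[float]
    out_dir: str = "fieldchm_out"
    pixel_size: float = 0.05
    central_mass: float = 0.999
    impute_window: int = 3
    rotation_deg: float = 0.0
    crop: tuple[int, int, int, int] | None = None
    expected_blocks: int | None = None
    expected_plots_per_block: int | None = None
    min_prominence: float = 0.1
    min_separation_px: int = 5
    correct_shear: bool = True
    shear_range: float = 0.2
    max_filter_window: int = 3
    margin_px: int = 2
    quantiles: tuple[float, ...] = chm_mod.DEFAULT_QUANTILES
    segmentation_reference: int = -1  # index into times; plots must be visible
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cloud_paths) != len(self.times):
            raise ValueError("cloud_paths and times must have equal length")
        if len(self.times) >= 2 and any(
            t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])
        ):
            raise ValueError("times must be strictly increasing")
        if len(set(self.cloud_paths)) != len(self.cloud_paths):
            raise ValueError("cloud paths must be distinct")


@dataclass
class PipelineResult:
    rasters: list[raster.ElevationRaster]  # imputed, metre-scale, ROI frame
    segmentation: geometry.PlotSegmentation
    chms: list[chm_mod.CanopyHeightModel]
    stats: list[chm_mod.PlotStats]
    fits: list[growth.LogisticFit]
    rgrs: list[growth.RgrValue]
    block_shears: dict[int, float] = field(default_factory=dict)


def rectify_blocks(
    rast: raster.ElevationRaster,
    block_rows: list[tuple[int, int]],
    shears: dict[int, float],
) -> raster.ElevationRaster:
    """Undo each block's skew by warping only that block's row band."""
    out = rast.copy()
    for b, (r0, r1) in enumerate(block_rows, start=1):
        s = shears.get(b, 0.0)
        if s == 0.0:
            continue
        band = replace(rast, values=rast.values[r0:r1], missing_mask=rast.missing_mask[r0:r1])
        warped = geometry.apply_affine(band, s)
        out.values[r0:r1] = warped.values
        out.missing_mask[r0:r1] = warped.missing_mask
    return out


def process_clouds(
    clouds: list[raster.PointCloud],
    times: list[float],
    *,
    pixel_size: float = 0.05,
    central_mass: float = 0.999,
    impute_window: int = 3,
    roi: geometry.RoiSpec | None = None,
    expected_blocks: int | None = None,
    expected_plots_per_block: int | None = None,
    min_prominence: float = 0.1,
    min_separation_px: int = 5,
    correct_shear: bool = True,
    shear_range: float = 0.2,
    max_filter_window: int = 3,
    margin_px: int = 2,
    quantiles: tuple[float, ...] = chm_mod.DEFAULT_QUANTILES,
    segmentation_reference: int = -1,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on in-memory point clouds.

    All flights are rasterized over the first flight's bounding box so the
    grids align pixel for pixel.  Segmentation runs on the height
    difference between a reference flight (default: the last, when plots
    are fully visible) and the first flight, which removes the terrain
    signal; the resulting rectangles transfer to every flight through the
    shared frame.  The first flight's raster is the DEM.
    """
    if len(clouds) != len(times):
        raise ValueError("need one cloud per time")
    if len(clouds) == 0:
        raise ValueError("no clouds supplied")

    t0 = _time.perf_counter()
    filtered = [raster.filter_outliers(c, central_mass) for c in clouds]
    log.info(
        "filter: kept %s of %s points (%.1fs)",
        sum(len(c) for c in filtered),
        sum(len(c) for c in clouds),
        _time.perf_counter() - t0,
    )

    pts0 = filtered[0].points
    bounds = (
        float(pts0[:, 0].min()), float(pts0[:, 0].max()),
        float(pts0[:, 1].min()), float(pts0[:, 1].max()),
    )
    t0 = _time.perf_counter()
    rasters = []
    for c in filtered:
        r = raster.rasterize(c, pixel_size, bounds=bounds)
        r, still_missing = raster.impute_missing(r, impute_window)
        rasters.append(r)
    log.info("rasterize+impute: %d rasters of %s px (%.1fs)",
             len(rasters), rasters[0].shape, _time.perf_counter() - t0)

    if roi is not None:
        rasters = [geometry.rotate_and_crop(r, roi) for r in rasters]

    ref = rasters[segmentation_reference]
    diff = replace(
        ref,
        values=ref.values - rasters[0].values,
        missing_mask=ref.missing_mask | rasters[0].missing_mask,
    )

    t0 = _time.perf_counter()
    row_prof = geometry.edge_profile(diff, "rows", min_prominence, min_separation_px)
    block_rows = list(zip(row_prof.left_edges, row_prof.right_edges))
    if expected_blocks is not None and len(block_rows) != expected_blocks:
        raise ValueError(f"detected {len(block_rows)} blocks, expected {expected_blocks}")

    shears: dict[int, float] = {}
    if correct_shear:
        for b, (r0, r1) in enumerate(block_rows, start=1):
            shears[b] = geometry.fit_parallelogram(
                diff, (int(r0), int(r1), 0, diff.shape[1]), shear_range=shear_range
            )
        diff = rectify_blocks(diff, block_rows, shears)
        rasters = [rectify_blocks(r, block_rows, shears) for r in rasters]

    plots: list[geometry.PlotRect] = []
    for b, (r0, r1) in enumerate(block_rows, start=1):
        sub = replace(diff, values=diff.values[r0:r1], missing_mask=diff.missing_mask[r0:r1])
        col_prof = geometry.edge_profile(sub, "cols", min_prominence, min_separation_px)
        intervals = list(zip(col_prof.left_edges, col_prof.right_edges))
        if expected_plots_per_block is not None and len(intervals) != expected_plots_per_block:
            raise ValueError(
                f"block {b}: detected {len(intervals)} plots, expected {expected_plots_per_block}"
            )
        for v, (c0, c1) in enumerate(intervals, start=1):
            plots.append(geometry.PlotRect(v, b, (int(r0), int(r1), int(c0), int(c1))))
    seg = geometry.PlotSegmentation(
        plots=plots,
        block_rows=[(int(a), int(b)) for a, b in block_rows],
        block_shear=shears or None,
    )
    log.info("segment: %d plots in %d blocks (%.1fs)",
             len(plots), len(block_rows), _time.perf_counter() - t0)

    t0 = _time.perf_counter()
    chms = [
        chm_mod.compute_chm(r, rasters[0], window=max_filter_window, time=t)
        for r, t in zip(rasters, times)
    ]
    stats: list[chm_mod.PlotStats] = []
    for c in chms:
        stats.extend(chm_mod.plot_statistics(c, seg, margin=margin_px, quantiles=quantiles))
    fits, rgrs = growth.fit_all(stats, seed=seed)
    log.info("chm+stats+fits: %d stats rows, %d/%d fits converged (%.1fs)",
             len(stats), sum(f.converged for f in fits), len(fits),
             _time.perf_counter() - t0)
    return PipelineResult(rasters, seg, chms, stats, fits, rgrs, shears)


# ---------------------------------------------------------------------------
# file-driven run


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "crop" in data and data["crop"] is not None:
        data["crop"] = tuple(data["crop"])
    if "quantiles" in data:
        data["quantiles"] = tuple(data["quantiles"])
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clouds = [raster.read_xyz(p) for p in config.cloud_paths]
    roi = geometry.RoiSpec(config.rotation_deg, config.crop)
    result = process_clouds(
        clouds,
        config.times,
        pixel_size=config.pixel_size,
        central_mass=config.central_mass,
        impute_window=config.impute_window,
        roi=roi,
        expected_blocks=config.expected_blocks,
        expected_plots_per_block=config.expected_plots_per_block,
        min_prominence=config.min_prominence,
        min_separation_px=config.min_separation_px,
        correct_shear=config.correct_shear,
        shear_range=config.shear_range,
        max_filter_window=config.max_filter_window,
        margin_px=config.margin_px,
        quantiles=config.quantiles,
        segmentation_reference=config.segmentation_reference,
        seed=config.seed,
    )

    artifacts: list[dict] = []

    def record(stage: str, path: Path) -> None:
        artifacts.append({"stage": stage, "path": str(path)})

    for i, (r, t) in enumerate(zip(result.rasters, config.times)):
        q = raster.quantize(r)
        png, sidecar = raster.write_png(q, out_dir / f"raster_t{i}.png")
        record("rasterize", png)
        record("rasterize", sidecar)
    seg_path = out_dir / "segmentation.json"
    seg_payload = {
        "plots": [
            {
                "variant": p.variant_index,
                "block": p.block_index,
                "rectangle": list(p.rectangle),
                "corners_m": _rect_corners_m(p, result.rasters[0]),
            }
            for p in result.segmentation.plots
        ],
        "block_rows": [list(b) for b in result.segmentation.block_rows],
        "block_shear": result.block_shears,
    }
    seg_path.write_text(json.dumps(seg_payload, indent=1))
    record("segment", seg_path)

    for i, c in enumerate(result.chms):
        chm_raster = raster.ElevationRaster(
            c.heights, np.zeros_like(c.heights, dtype=bool),
            origin=c.origin, pixel_size=c.pixel_size,
        )
        png, sidecar = raster.write_png(raster.quantize(chm_raster), out_dir / f"chm_t{i}.png")
        record("chm", png)
        record("chm", sidecar)

    stats_path = out_dir / "plot_stats.csv"
    chm_mod.stats_to_frame(result.stats).to_csv(stats_path, index=False)
    record("stats", stats_path)
    fits_path = out_dir / "logistic_fits.csv"
    growth.fits_to_frame(result.fits).to_csv(fits_path, index=False)
    record("growth", fits_path)
    rgr_path = out_dir / "rgr.csv"
    growth.rgr_to_frame(result.rgrs).to_csv(rgr_path, index=False)
    record("growth", rgr_path)

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "input_hashes": {p: _sha256(Path(p)) for p in config.cloud_paths},
        "artifacts": artifacts,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _rect_corners_m(p: geometry.PlotRect, r: raster.ElevationRaster) -> list[list[float]]:
    r0, r1, c0, c1 = p.rectangle
    x0 = r.origin[0] + c0 * r.pixel_size
    x1 = r.origin[0] + c1 * r.pixel_size
    y0 = r.origin[1] - r1 * r.pixel_size
    y1 = r.origin[1] - r0 * r.pixel_size
    return [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]


def validate_against_reference(
    stats: list[chm_mod.PlotStats] | pd.DataFrame,
    reference: pd.DataFrame,
) -> tuple[float, dict[int, float]]:
    """RMSD of computed per-plot median height against reference heights.

    ``reference`` columns: variant, block, time_days, height — one row per
    manual measurement point (several points per plot are fine; each is
    compared with that plot's computed median).  Returns the overall RMSD
    in metres and a per-block breakdown.
    """
    if isinstance(stats, list):
        stats = chm_mod.stats_to_frame(stats)
    med = stats[stats["stat_name"] == "median"]
    merged = reference.merge(
        med, on=["variant", "block", "time_days"], how="inner", suffixes=("_ref", "")
    )
    if merged.empty:
        raise ValueError("no reference rows match the computed statistics")
    err = merged["value"] - merged["height"]
    rmsd = float(np.sqrt(np.mean(err**2)))
    per_block = {
        int(b): float(np.sqrt(np.mean(g**2)))
        for b, g in err.groupby(merged["block"])
    }
    return rmsd, per_block
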