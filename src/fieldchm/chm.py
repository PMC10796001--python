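"""Canopy height model construction and per-plot height statistics.

The crop height model (CHM) is the normalized surface model: the canopy
top surface of a flight minus the bare-ground elevation (DEM) of the
pre-emergence flight.  Because neighbouring pixels sample different parts
of plants, the raw raster is noisy; a morphological maximum filter (the
"deformable blanket") traces the canopy top before the DEM subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import PlotSegmentation, shrink_rectangles
from .raster import ElevationRaster

__all__ = [
    "CanopyHeightModel",
    "PlotStats",
    "max_filter",
    "compute_chm",
    "plot_statistics",
    "stats_to_frame",
    "DEFAULT_QUANTILES",
]

DEFAULT_QUANTILES = (0.1, 0.25, 0.75, 0.9)


@dataclass
class CanopyHeightModel:
    """Canopy height above time-zero ground, metres, on the raster grid."""

    heights: np.ndarray
    time: float  # days since the first flight
    origin: tuple[float, float]
    pixel_size: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("CHM heights must be finite")


@dataclass(frozen=True)
class PlotStats:
    variant_index: int
    block_index: int
    time: float
    mean: float
    sd: float
    median: float
    min: float
    max: float
    quantiles: dict[float, float]


def max_filter(raster: ElevationRaster, window: int = 3) -> ElevationRaster:
    """Replace each pixel by the maximum over its ``window x window``
    neighbourhood (edge pixels use the in-bounds part); window 1 is the
    identity."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return raster.copy()
    if raster.missing_mask.any():
        raise ValueError("max_filter requires a fully defined raster")
    # 'nearest' replication never exceeds the in-bounds window maximum
    filtered = ndimage.maximum_filter(raster.values, size=window, mode="nearest")
    return replace(raster, values=filtered, missing_mask=raster.missing_mask.copy())


def compute_chm(
    raster_t: ElevationRaster,
    dem_t0: ElevationRaster,
    window: int = 3,
    time: float = 0.0,
    max_filter_dem: bool = False,
) -> CanopyHeightModel:
    """CHM = max_filter(raster_t) - DEM, clamped below at zero.

    The DEM is the imputed first-flight raster; it is left unfiltered by
    default so the ground reference is not inflated by the dilation.
    """
    if raster_t.shape != dem_t0.shape:
        raise ValueError(f"shape mismatch: {raster_t.shape} vs {dem_t0.shape}")
    if raster_t.origin != dem_t0.origin or raster_t.pixel_size != dem_t0.pixel_size:
        raise ValueError("rasters are not on the same georeferenced grid")
    if raster_t.quantized or dem_t0.quantized:
        raise ValueError("compute_chm expects dequantized (metre-scale) rasters")
    top = max_filter(raster_t, window)
    dem = max_filter(dem_t0, window) if max_filter_dem else dem_t0
    heights = np.maximum(top.values - dem.values, 0.0)
    return CanopyHeightModel(
        heights=heights, time=time, origin=raster_t.origin, pixel_size=raster_t.pixel_size
    )


def plot_statistics(
    chm: CanopyHeightModel,
    seg: PlotSegmentation,
    margin: int = 2,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> list[PlotStats]:
    """Summary statistics of CHM pixels inside each margin-shrunken plot.

    The margin drops edge pixels straddling the plot/alley boundary.
    Quantiles use linear interpolation between order statistics.
    """
    n_rows, n_cols = chm.heights.shape
    for p in seg.plots:
        r0, r1, c0, c1 = p.rectangle
        if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
            raise ValueError(f"plot rectangle {p.rectangle} outside CHM bounds")
    inner = shrink_rectangles(seg, margin)
    out = []
    for p in inner.plots:
        px = chm.heights[p.rows, p.cols].ravel()
        qs = {float(q): float(np.quantile(px, q)) for q in quantiles}
        out.append(
            PlotStats(
                variant_index=p.variant_index,
                block_index=p.block_index,
                time=chm.time,
                mean=float(px.mean()),
                sd=float(px.std(ddof=0)),
                median=float(np.median(px)),
                min=float(px.min()),
                max=float(px.max()),
                quantiles=qs,
            )
        )
    return out


def stats_to_frame(stats: list[PlotStats]) -> pd.DataFrame:
    """Long-format table: variant, block, time_days, stat_name, value."""
    rows = []
    for s in stats:
        base = {"variant": s.variant_index, "block": s.block_index, "time_days": s.time}
        for name in ("mean", "sd", "median", "min", "max"):
            rows.append({**base, "stat_name": name, "value": getattr(s, name)})
        for q, v in s.quantiles.items():
            rows.append({**base, "stat_name": f"q{q:g}", "value": v})
    return pd.DataFrame(rows)
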