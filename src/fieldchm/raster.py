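"""Point-cloud filtering and conversion to 16-bit elevation rasters.

A LiDAR flight yields an unordered list of ``(x, y, z)`` returns in a
projected metric frame.  This module turns such a cloud into a "2.5D"
elevation image: outliers are trimmed by empirical quantiles, points are
binned onto a uniform grid (per-pixel mean of z), holes are filled by an
iterated masked median filter, and the result is quantized to 16-bit
levels so it can be stored as a plain greyscale PNG with a small JSON
sidecar carrying the georeference and the quantization metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PointCloud",
    "ElevationRaster",
    "filter_outliers",
    "rasterize",
    "impute_missing",
    "quantize",
    "dequantize",
    "write_png",
    "read_png",
    "read_xyz",
    "write_xyz",
]

N_LEVELS = 65536  # 16-bit depth


@dataclass(frozen=True)
class PointCloud:
    """Unordered 3D returns, ``points`` is an (n, 3) float array of x, y, z in metres."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be an (n, 3) array, got shape {pts.shape}")
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ElevationRaster:
    """2D elevation grid with georeference and quantization metadata.

    ``values[r, c]`` is the elevation of the pixel whose upper-left corner is at
    ``(origin_x + c*pixel_size, origin_y - r*pixel_size)``; row 0 is the
    northernmost row.  Values are metres when ``quantized`` is False and
    integer 16-bit levels otherwise (``z = z_min + level * z_scale``).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    origin: tuple[float, float]  # (x_min, y_max)
    pixel_size: float
    z_min: float = 0.0
    z_scale: float = 1.0
    quantized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def defined(self) -> np.ndarray:
        return ~self.missing_mask

    def copy(self) -> "ElevationRaster":
        return replace(self, values=self.values.copy(), missing_mask=self.missing_mask.copy())


# ---------------------------------------------------------------------------
# point-cloud operations


def filter_outliers(cloud: PointCloud, central_mass: float = 0.999) -> PointCloud:
    """Drop points outside the central ``central_mass`` quantile interval.

    A point survives only if its x, y and z each lie inside the two-sided
    empirical interval ``[q_lo, q_hi]`` with ``lo = (1 - central_mass)/2``,
    which trims isolated returns (birds, multipath) from both tails.
    """
    if len(cloud) == 0:
        raise ValueError("cannot filter an empty point cloud")
    if not 0 < central_mass <= 1:
        raise ValueError("central_mass must be in (0, 1]")
    if central_mass == 1.0:
        return cloud
    lo = (1.0 - central_mass) / 2.0
    pts = cloud.points
    keep = np.ones(len(cloud), dtype=bool)
    for axis in range(3):
        q_lo, q_hi = np.quantile(pts[:, axis], [lo, 1.0 - lo])
        keep &= (pts[:, axis] >= q_lo) & (pts[:, axis] <= q_hi)
    return PointCloud(pts[keep])


def rasterize(
    cloud: PointCloud,
    pixel_size: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> ElevationRaster:
    """Bin points onto a uniform grid; each pixel is the mean z of its points.

    The grid spans the cloud's x-y bounding box unless ``bounds``
    (x_min, x_max, y_min, y_max) is given, in which case points outside are
    dropped — passing the time-zero bounds to every flight puts all rasters
    on one shared pixel grid.  Pixel (r, c) covers the half-open square
    ``[x_min + c*p, x_min + (c+1)*p) x (y_max - (r+1)*p, y_max - r*p]``.
    """
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty point cloud")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    pts = cloud.points
    if bounds is None:
        x_min, x_max = pts[:, 0].min(), pts[:, 0].max()
        y_min, y_max = pts[:, 1].min(), pts[:, 1].max()
    else:
        x_min, x_max, y_min, y_max = bounds
        inside = (
            (pts[:, 0] >= x_min) & (pts[:, 0] <= x_max)
            & (pts[:, 1] >= y_min) & (pts[:, 1] <= y_max)
        )
        pts = pts[inside]
        if pts.shape[0] == 0:
            raise ValueError("no points fall inside the requested bounds")
    n_cols = max(1, int(np.ceil((x_max - x_min) / pixel_size - 1e-9)))
    n_rows = max(1, int(np.ceil((y_max - y_min) / pixel_size - 1e-9)))
    col = np.clip(((pts[:, 0] - x_min) / pixel_size).astype(int), 0, n_cols - 1)
    row = np.clip(((y_max - pts[:, 1]) / pixel_size).astype(int), 0, n_rows - 1)
    flat = row * n_cols + col
    counts = np.bincount(flat, minlength=n_rows * n_cols)
    sums = np.bincount(flat, weights=pts[:, 2], minlength=n_rows * n_cols)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    values = means.reshape(n_rows, n_cols)
    missing = counts.reshape(n_rows, n_cols) == 0
    values[missing] = 0.0
    return ElevationRaster(values, missing, origin=(float(x_min), float(y_max)), pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# raster operations


def _masked_median_pass(values: np.ndarray, missing: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """One imputation sweep: fill each missing pixel that has a defined
    neighbour in its window with the median of those defined values."""
    half = window // 2
    padded = np.pad(values.astype(float), half, constant_values=np.nan)
    padded[np.pad(missing, half, constant_values=True)] = np.nan
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    win = win.reshape(values.shape[0], values.shape[1], -1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows are expected
        med = np.nanmedian(win, axis=-1)
    fillable = missing & np.isfinite(med)
    out = values.copy()
    out[fillable] = med[fillable]
    return out, missing & ~fillable


def impute_missing(raster: ElevationRaster, window: int = 3) -> tuple[ElevationRaster, int]:
    """Fill missing pixels by an iterated neighbourhood median.

    Each pass replaces every missing pixel that has at least one defined
    neighbour in its ``window x window`` neighbourhood by the median of the
    defined values there; defined pixels never change.  Passes repeat until
    no pixel can be filled.  Returns the imputed raster and the count of
    pixels still missing (isolated only when the defined set is not
    connected to them at all, which cannot happen on a finite grid — the
    count is 0 unless the raster started fully missing).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not raster.defined().any():
        raise ValueError("cannot impute a raster with no defined pixels")
    values = raster.values.copy()
    missing = raster.missing_mask.copy()
    while missing.any():
        values, new_missing = _masked_median_pass(values, missing, window)
        if new_missing.sum() == missing.sum():  # no progress
            break
        missing = new_missing
    out = replace(raster, values=values, missing_mask=missing)
    return out, int(missing.sum())


def quantize(raster: ElevationRaster) -> ElevationRaster:
    """Map elevations to 16-bit levels: ``level = round((z - z_min)/z_scale)``.

    ``z_scale = (z_max - z_min)/65535`` so the defined range fills the full
    bit depth; a constant raster gets z_scale = 1 and all-zero levels.
    When the raster still has missing pixels one level is held back
    (``z_scale = range/65534``) so the PNG encoding can reserve a level
    for "missing" without clipping the top of the range.
    """
    if raster.quantized:
        raise ValueError("raster is already quantized")
    defined = raster.defined()
    if not defined.any():
        raise ValueError("cannot quantize a raster with no defined pixels")
    z = raster.values[defined]
    z_min, z_max = float(z.min()), float(z.max())
    top = N_LEVELS - 2 if raster.missing_mask.any() else N_LEVELS - 1
    z_scale = (z_max - z_min) / top if z_max > z_min else 1.0
    levels = np.zeros_like(raster.values)
    levels[defined] = np.round((z - z_min) / z_scale)
    return replace(
        raster,
        values=levels,
        missing_mask=raster.missing_mask.copy(),
        z_min=z_min,
        z_scale=z_scale,
        quantized=True,
    )


def dequantize(raster: ElevationRaster) -> ElevationRaster:
    """Invert :func:`quantize`: ``z = z_min + level * z_scale``."""
    if not raster.quantized:
        raise ValueError("raster is not quantized")
    if raster.z_scale <= 0:
        raise ValueError("invalid quantization metadata (z_scale <= 0)")
    values = raster.z_min + raster.values * raster.z_scale
    values[raster.missing_mask] = 0.0
    return replace(
        raster,
        values=values,
        missing_mask=raster.missing_mask.copy(),
        quantized=False,
    )


# ---------------------------------------------------------------------------
# file formats


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_png(raster: ElevationRaster, path: str | Path) -> tuple[Path, Path]:
    """Write a quantized raster as 16-bit greyscale PNG + JSON sidecar.

    If the raster has missing pixels, defined levels are shifted up by one
    and level 0 is reserved for "missing"; the shift is recorded in the
    sidecar and undone on read, so the round-trip is bit-exact.
    """
    if not raster.quantized:
        raise ValueError("write_png requires a quantized raster")
    path = Path(path)
    levels = raster.values.astype(np.int64)
    has_missing = bool(raster.missing_mask.any())
    offset = 0
    missing_level = None
    if has_missing:
        if levels[raster.defined()].max(initial=0) >= N_LEVELS - 1:
            raise ValueError(
                "raster uses level 65535 and has missing pixels; impute before writing"
            )
        offset = 1
        missing_level = 0
        levels = levels + offset
        levels[raster.missing_mask] = missing_level
    iio.imwrite(path, levels.astype(np.uint16), extension=".png")
    sidecar = _sidecar_path(path)
    meta = {
        "origin_x": raster.origin[0],
        "origin_y": raster.origin[1],
        "pixel_size": raster.pixel_size,
        "z_min": raster.z_min,
        "z_scale": raster.z_scale,
        "level_offset": offset,
        "missing_level": missing_level,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar


def read_png(path: str | Path) -> ElevationRaster:
    """Read a 16-bit PNG + sidecar written by :func:`write_png`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = iio.imread(path)
    if img.dtype != np.uint16:
        raise ValueError(f"{path} is not a 16-bit greyscale PNG (dtype {img.dtype})")
    levels = img.astype(np.int64)
    missing_level = meta.get("missing_level")
    offset = int(meta.get("level_offset", 0))
    if missing_level is not None:
        missing = levels == missing_level
    else:
        missing = np.zeros_like(levels, dtype=bool)
    values = (levels - offset).astype(float)
    values[missing] = 0.0
    return ElevationRaster(
        values,
        missing,
        origin=(float(meta["origin_x"]), float(meta["origin_y"])),
        pixel_size=float(meta["pixel_size"]),
        z_min=float(meta["z_min"]),
        z_scale=float(meta["z_scale"]),
        quantized=True,
    )


def read_xyz(path: str | Path) -> PointCloud:
    """Read the plain text dialect: one ``x y z`` (or comma-separated) per line."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    pts = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    return PointCloud(pts)


def write_xyz(cloud: PointCloud, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, cloud.points, fmt="%.6f")
    return path
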