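"""ROI selection, plot instance segmentation and skew rectification.

Field plots are thin rectangles laid out on a grid, so their boundaries
show up as steps in the image's projection profiles: summing pixel values
along one axis gives a 1D profile whose first differences peak at plot
edges.  Blocks are found the same way on the orthogonal axis.  Sowing
drift skews plot columns into parallelograms; a one-parameter shear that
maximizes the sharpness of the rectified column profile is estimated per
block and undone with an affine row-shift warp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .raster import ElevationRaster

__all__ = [
    "RoiSpec",
    "PlotRect",
    "PlotSegmentation",
    "EdgeProfile",
    "rotate_and_crop",
    "edge_profile",
    "segment_plots",
    "fit_parallelogram",
    "apply_affine",
    "shrink_rectangles",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rotation (degrees CCW about the raster centre) then pixel crop.

    ``crop`` is (row_start, row_stop, col_start, col_stop), half-open, in
    the rotated raster's pixel coordinates; None keeps the full extent.
    """

    rotation_deg: float = 0.0
    crop: tuple[int, int, int, int] | None = None


@dataclass(frozen=True)
class PlotRect:
    variant_index: int
    block_index: int
    rectangle: tuple[int, int, int, int]  # (row_start, row_stop, col_start, col_stop)

    @property
    def rows(self) -> slice:
        return slice(self.rectangle[0], self.rectangle[1])

    @property
    def cols(self) -> slice:
        return slice(self.rectangle[2], self.rectangle[3])


@dataclass
class PlotSegmentation:
    plots: list[PlotRect]
    block_rows: list[tuple[int, int]]  # (row_start, row_stop) per block, top first
    block_shear: dict[int, float] | None = None  # block_index -> shear (px col / px row)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.plots:
            key = (p.variant_index, p.block_index)
            if key in seen:
                raise ValueError(f"duplicate plot index {key}")
            seen.add(key)

    def rect(self, variant: int, block: int) -> PlotRect:
        for p in self.plots:
            if p.variant_index == variant and p.block_index == block:
                return p
        raise KeyError((variant, block))


@dataclass(frozen=True)
class EdgeProfile:
    sums: np.ndarray  # normalized per-line means, in [0, 1]
    derivative: np.ndarray  # first differences, len(sums) - 1
    left_edges: np.ndarray  # start positions (inclusive)
    right_edges: np.ndarray  # stop positions (exclusive)


def rotate_and_crop(raster: ElevationRaster, roi: RoiSpec) -> ElevationRaster:
    """Rotate the raster CCW about its centre, then crop to the ROI.

    Exact for multiples of 90 degrees; bilinear interpolation otherwise,
    with pixels that sample outside the original grid marked missing.
    The origin is updated so that crops of a shared frame stay aligned
    across time points (rotation keeps the pixel size).
    """
    values = raster.values.astype(float).copy()
    missing = raster.missing_mask.copy()
    angle = roi.rotation_deg % 360.0
    if angle != 0.0:
        if angle % 90.0 == 0.0:
            k = int(angle // 90) % 4
            values = np.rot90(values, k)
            missing = np.rot90(missing, k)
        else:
            work = values.copy()
            work[missing] = np.nan
            values = ndimage.rotate(work, angle, reshape=True, order=1, cval=np.nan)
            missing = ~np.isfinite(values)
            values[missing] = 0.0
    n_rows, n_cols = values.shape
    if roi.crop is not None:
        r0, r1, c0, c1 = roi.crop
        if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
            raise ValueError(
                f"crop {roi.crop} outside rotated raster bounds {(n_rows, n_cols)}"
            )
        values = values[r0:r1, c0:c1]
        missing = missing[r0:r1, c0:c1]
    else:
        r0, c0 = 0, 0
    origin = (
        raster.origin[0] + c0 * raster.pixel_size,
        raster.origin[1] - r0 * raster.pixel_size,
    )
    return replace(raster, values=values, missing_mask=missing, origin=origin)


def edge_profile(
    raster: ElevationRaster,
    axis: str = "cols",
    min_prominence: float = 0.1,
    min_separation: int = 5,
) -> EdgeProfile:
    """Detect plot (or block) edges from a summed projection profile.

    ``axis="cols"`` averages each column (finding vertical edges between
    side-by-side plots); ``axis="rows"`` averages each row (finding block
    boundaries).  The profile is min-max normalized; a left edge is a
    positive peak of its first difference and a right edge a negative
    peak, each of prominence at least ``min_prominence`` and separated by
    ``min_separation`` samples from peaks of the same sign.
    """
    if raster.missing_mask.any():
        raise ValueError("edge_profile requires a fully defined (imputed) raster")
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    sums = raster.values.mean(axis=0 if axis == "cols" else 1)
    if sums.size < 2:
        raise ValueError("profile needs at least 2 samples")
    rng = sums.max() - sums.min()
    if rng <= 0:
        raise ValueError("flat profile: no edges detectable")
    sums = (sums - sums.min()) / rng
    deriv = np.diff(sums)
    up, _ = signal.find_peaks(deriv, prominence=min_prominence, distance=min_separation)
    down, _ = signal.find_peaks(-deriv, prominence=min_prominence, distance=min_separation)
    if up.size == 0 or down.size == 0:
        raise ValueError("no edges found in profile")
    # pair each rising edge with the first falling edge after it
    lefts, rights = [], []
    di = 0
    for u in up:
        while di < down.size and down[di] <= u:
            di += 1
        if di == down.size:
            break
        lefts.append(u + 1)  # step between u and u+1 -> interval starts at u+1
        rights.append(down[di] + 1)  # interval stops before down+1
        di += 1
    if not lefts:
        raise ValueError("edges found but none form a (left, right) interval")
    return EdgeProfile(
        sums=sums,
        derivative=deriv,
        left_edges=np.asarray(lefts, dtype=int),
        right_edges=np.asarray(rights, dtype=int),
    )


def segment_plots(
    raster: ElevationRaster,
    expected_blocks: int | None = None,
    expected_plots_per_block: int | None = None,
    min_prominence: float = 0.1,
    min_separation: int = 5,
) -> PlotSegmentation:
    """Split the ROI into per-plot rectangles.

    Row-axis edges delimit blocks (top block first); within each block the
    column-axis profile delimits plots (variant 1 leftmost).  When
    expected counts are supplied, any disagreement with the detected
    counts raises with both numbers in the message.
    """
    row_prof = edge_profile(raster, "rows", min_prominence, min_separation)
    blocks = list(zip(row_prof.left_edges, row_prof.right_edges))
    if expected_blocks is not None and len(blocks) != expected_blocks:
        raise ValueError(f"detected {len(blocks)} blocks, expected {expected_blocks}")
    plots: list[PlotRect] = []
    for b, (r0, r1) in enumerate(blocks, start=1):
        sub = replace(
            raster,
            values=raster.values[r0:r1],
            missing_mask=raster.missing_mask[r0:r1],
        )
        col_prof = edge_profile(sub, "cols", min_prominence, min_separation)
        intervals = list(zip(col_prof.left_edges, col_prof.right_edges))
        if expected_plots_per_block is not None and len(intervals) != expected_plots_per_block:
            raise ValueError(
                f"block {b}: detected {len(intervals)} plots, "
                f"expected {expected_plots_per_block}"
            )
        for v, (c0, c1) in enumerate(intervals, start=1):
            plots.append(PlotRect(v, b, (int(r0), int(r1), int(c0), int(c1))))
    _check_disjoint(plots)
    return PlotSegmentation(plots=plots, block_rows=[(int(a), int(b)) for a, b in blocks])


def _check_disjoint(plots: list[PlotRect]) -> None:
    for i, p in enumerate(plots):
        for q in plots[i + 1:]:
            r0, r1, c0, c1 = p.rectangle
            s0, s1, d0, d1 = q.rectangle
            if r0 < s1 and s0 < r1 and c0 < d1 and d0 < c1:
                raise ValueError(f"overlapping rectangles: {p} and {q}")


def _sheared_column_profile(values: np.ndarray, shear: float) -> np.ndarray:
    """Column means after shifting row r horizontally by -shear * (r - r_ref)."""
    n_rows, n_cols = values.shape
    ref = (n_rows - 1) / 2.0
    acc = np.zeros(n_cols)
    wacc = np.zeros(n_cols)
    cols = np.arange(n_cols, dtype=float)
    for r in range(n_rows):
        src = cols + shear * (r - ref)  # sample position in the original row
        acc += np.interp(src, cols, values[r], left=values[r, 0], right=values[r, -1])
        wacc += 1.0
    return acc / wacc


def _profile_sharpness(values: np.ndarray, shear: float) -> float:
    prof = _sheared_column_profile(values, shear)
    return float(np.sum(np.diff(prof) ** 2))


def fit_parallelogram(
    raster: ElevationRaster,
    block_rect: tuple[int, int, int, int] | None = None,
    shear_range: float = 0.2,
    coarse_steps: int = 41,
) -> float:
    """Estimate the shear (column offset per row, px/px) of a skewed block.

    Searches the shear that maximizes the sharpness (sum of squared first
    differences) of the column-sum profile recomputed after rectifying
    rows: a grid scan over ``[-shear_range, shear_range]`` refined by
    golden-section search around the best candidate.
    """
    values = raster.values
    if block_rect is not None:
        r0, r1, c0, c1 = block_rect
        values = values[r0:r1, c0:c1]
    if values.size == 0 or values.max() == values.min():
        raise ValueError("degenerate block: uniform or empty values")
    shears = np.linspace(-shear_range, shear_range, coarse_steps)
    scores = [_profile_sharpness(values, s) for s in shears]
    best = int(np.argmax(scores))
    lo = shears[max(0, best - 1)]
    hi = shears[min(len(shears) - 1, best + 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda s: -_profile_sharpness(values, s),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def apply_affine(raster: ElevationRaster, shear: float) -> ElevationRaster:
    """Rectify skew: shift row r horizontally by ``-shear * (r - r_ref)``.

    Linear interpolation; the output has the input's shape, edge values
    extend beyond the original support.  ``apply_affine(apply_affine(x, s), -s)``
    recovers x up to interpolation error.
    """
    if not np.isfinite(shear):
        raise ValueError("shear must be finite")
    values = raster.values
    n_rows, n_cols = values.shape
    ref = (n_rows - 1) / 2.0
    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    src_cols = cols + shear * (rows - ref)
    src_rows = np.broadcast_to(rows, src_cols.shape)
    warped = ndimage.map_coordinates(
        values, [src_rows, src_cols], order=1, mode="nearest"
    )
    miss = ndimage.map_coordinates(
        raster.missing_mask.astype(float), [src_rows, src_cols], order=0, mode="nearest"
    ).astype(bool)
    return replace(raster, values=warped, missing_mask=miss)


def shrink_rectangles(seg: PlotSegmentation, margin: int) -> PlotSegmentation:
    """Inset every plot rectangle by ``margin`` pixels on all four sides."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return seg
    shrunk = []
    for p in seg.plots:
        r0, r1, c0, c1 = p.rectangle
        r0, r1, c0, c1 = r0 + margin, r1 - margin, c0 + margin, c1 - margin
        if r0 >= r1 or c0 >= c1:
            raise ValueError(
                f"margin {margin} collapses plot (variant {p.variant_index}, "
                f"block {p.block_index}) rectangle {p.rectangle}"
            )
        shrunk.append(PlotRect(p.variant_index, p.block_index, (r0, r1, c0, c1)))
    return PlotSegmentation(plots=shrunk, block_rows=seg.block_rows, block_shear=seg.block_shear)
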