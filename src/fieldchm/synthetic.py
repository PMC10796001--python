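"""Synthetic multi-temporal LiDAR scans of a field-plot trial.

Generates point clouds of a rectangular array of sown plots — blocks of
thin, long plots separated by bare alleys on a gently undulating terrain —
at a sequence of flight dates.  Each plot's canopy top follows a
three-parameter logistic trajectory S(t) = A / (1 + exp(-B t - C)), so the
per-plot height at every time is known exactly and the whole pipeline can
be validated against ground truth without any field data.

The default design mirrors a barley variety trial: 3 blocks of 48 plots,
each plot 1.2 m wide and 9 m long.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster import PointCloud

__all__ = ["FieldDesign", "PlotTruth", "generate_field", "write_truth_table", "read_truth_table"]


@dataclass(frozen=True)
class FieldDesign:
    """Layout and noise model of the simulated trial.

    ``skew_shear`` is the lateral (x) offset of plot corners per metre of
    plot length (y), mimicking sowing drift; ``terrain_amplitude_m`` and
    ``terrain_wavelength_m`` control the smooth two-sinusoid ground
    surface; ``point_density_per_m2`` is the mean LiDAR return density.
    """

    n_blocks: int = 3
    plots_per_block: int = 48
    plot_length_m: float = 9.0
    plot_width_m: float = 1.2
    alley_width_m: float = 0.6
    skew_shear: float = 0.0
    terrain_amplitude_m: float = 0.2
    terrain_wavelength_m: float = 30.0
    point_density_per_m2: float = 200.0
    noise_sd_m: float = 0.03
    border_m: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plot_length_m", "plot_width_m", "alley_width_m", "point_density_per_m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_blocks < 1 or self.plots_per_block < 1:
            raise ValueError("need at least one block and one plot per block")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be non-negative")

    @property
    def field_width_m(self) -> float:
        n = self.plots_per_block
        return n * self.plot_width_m + (n - 1) * self.alley_width_m

    @property
    def field_height_m(self) -> float:
        return self.n_blocks * self.plot_length_m + (self.n_blocks - 1) * self.alley_width_m

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the scanned area including border."""
        return (
            -self.border_m,
            self.field_width_m + self.border_m,
            -self.border_m,
            self.field_height_m + self.border_m,
        )


@dataclass(frozen=True)
class PlotTruth:
    """Ground truth for one plot: its footprint and logistic parameters."""

    variant_index: int  # 1-based, left to right within the block
    block_index: int  # 1-based, top (north) block first
    corner_coordinates: tuple[tuple[float, float], ...]  # 4 x (x, y), metres
    logistic_params: tuple[float, float, float]  # (A metres, B per-day, C dimensionless)

    def height_at(self, t: float) -> float:
        a, b, c = self.logistic_params
        return a / (1.0 + np.exp(-b * t - c))

    @property
    def centre(self) -> tuple[float, float]:
        xs = [p[0] for p in self.corner_coordinates]
        ys = [p[1] for p in self.corner_coordinates]
        return (sum(xs) / 4.0, sum(ys) / 4.0)


def terrain_height(design: FieldDesign, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth ground surface: sum of two orthogonal sinusoids."""
    a = design.terrain_amplitude_m / 2.0
    k = 2.0 * np.pi / design.terrain_wavelength_m
    return a * (np.sin(k * x) + np.sin(0.7 * k * y))


def _plot_layout(design: FieldDesign, rng: np.random.Generator) -> list[PlotTruth]:
    """Plot footprints plus per-plot logistic parameters.

    The asymptotic height A varies smoothly across the field (a long-wave
    fertility pattern) with small per-plot jitter, so parameter heat maps
    have recoverable spatial structure; B and C get independent jitter.
    """
    truths: list[PlotTruth] = []
    pitch_x = design.plot_width_m + design.alley_width_m
    pitch_y = design.plot_length_m + design.alley_width_m
    for b in range(design.n_blocks):
        # block b occupies rows from the top: block 1 is northernmost
        y_top = design.field_height_m - b * pitch_y
        y_bot = y_top - design.plot_length_m
        for v in range(design.plots_per_block):
            x0 = v * pitch_x
            x1 = x0 + design.plot_width_m
            cx, cy = (x0 + x1) / 2.0, (y_bot + y_top) / 2.0
            a_smooth = 0.80 + 0.12 * np.sin(2 * np.pi * cx / (design.field_width_m + 1e-9)) \
                + 0.06 * np.cos(2 * np.pi * cy / (design.field_height_m + 1e-9))
            a_param = max(0.3, a_smooth + rng.normal(0.0, 0.02))
            b_param = max(0.05, 0.15 + rng.normal(0.0, 0.01))
            c_param = -6.0 + rng.normal(0.0, 0.3)
            # shear displaces corners in x proportionally to height above the block base
            s = design.skew_shear
            corners = (
                (x0, y_bot),
                (x1, y_bot),
                (x1 + s * design.plot_length_m, y_top),
                (x0 + s * design.plot_length_m, y_top),
            )
            truths.append(
                PlotTruth(
                    variant_index=v + 1,
                    block_index=b + 1,
                    corner_coordinates=corners,
                    logistic_params=(float(a_param), float(b_param), float(c_param)),
                )
            )
    return truths


def generate_field(
    design: FieldDesign,
    times: list[float],
    logistic_overrides: dict[tuple[int, int], tuple[float, float, float]] | None = None,
) -> tuple[list[PointCloud], list[PlotTruth]]:
    """Simulate one point cloud per flight date.

    Points are scattered uniformly over the field extent at the design
    density.  A point falling inside a plot footprint samples the canopy
    top, terrain + S(t) for that plot's logistic parameters; alley and
    border points sample the bare terrain.  All z values get additive
    Gaussian noise of sd ``noise_sd_m``.  Identical design + times + seed
    reproduce the clouds bit for bit.

    ``logistic_overrides`` maps (variant_index, block_index) to (A, B, C)
    for tests that need exact, hand-chosen trajectories.
    """
    times = list(times)
    if not times:
        raise ValueError("times must be non-empty")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")

    rng = np.random.default_rng(design.seed)
    truths = _plot_layout(design, rng)
    if logistic_overrides:
        truths = [
            PlotTruth(
                t.variant_index,
                t.block_index,
                t.corner_coordinates,
                logistic_overrides.get((t.variant_index, t.block_index), t.logistic_params),
            )
            for t in truths
        ]

    x_min, x_max, y_min, y_max = design.extent
    area = (x_max - x_min) * (y_max - y_min)
    n_points = rng.poisson(design.point_density_per_m2 * area)

    pitch_x = design.plot_width_m + design.alley_width_m
    pitch_y = design.plot_length_m + design.alley_width_m

    clouds: list[PointCloud] = []
    for t in times:
        xs = rng.uniform(x_min, x_max, size=n_points)
        ys = rng.uniform(y_min, y_max, size=n_points)
        z = terrain_height(design, xs, ys)

        # locate each point's plot (if any) by inverting the regular layout
        # blocks count from the top; ys measured from field bottom (0)
        row_from_top = (design.field_height_m - ys) / pitch_y
        block = np.floor(row_from_top).astype(int)
        y_in_block = design.field_height_m - ys - block * pitch_y  # 0 at block top
        in_block = (block >= 0) & (block < design.n_blocks) & (y_in_block <= design.plot_length_m)

        # undo shear before the column test; shear grows from the block base (bottom)
        height_above_base = np.clip(design.plot_length_m - y_in_block, 0.0, design.plot_length_m)
        x_rect = xs - design.skew_shear * height_above_base
        col = np.floor(x_rect / pitch_x).astype(int)
        x_in_col = x_rect - col * pitch_x
        in_plot = (
            in_block
            & (col >= 0)
            & (col < design.plots_per_block)
            & (x_in_col <= design.plot_width_m)
        )

        canopy = np.zeros(n_points)
        if in_plot.any():
            plot_idx = block * design.plots_per_block + col
            heights = np.array([tr.height_at(t) for tr in truths])
            canopy[in_plot] = heights[plot_idx[in_plot]]
        z = z + canopy
        if design.noise_sd_m > 0:
            z = z + rng.normal(0.0, design.noise_sd_m, size=n_points)
        clouds.append(PointCloud(np.column_stack([xs, ys, z])))
    return clouds, truths


def write_truth_table(truth: list[PlotTruth], path: str | Path) -> Path:
    """One CSV row per plot: indices, the 4 corners, and (A, B, C)."""
    if not truth:
        raise ValueError("truth list is empty")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["variant", "block"]
        for i in range(4):
            header += [f"x{i}", f"y{i}"]
        header += ["A", "B", "C"]
        writer.writerow(header)
        for t in truth:
            row = [t.variant_index, t.block_index]
            for x, y in t.corner_coordinates:
                row += [repr(x), repr(y)]
            row += [repr(v) for v in t.logistic_params]
            writer.writerow(row)
    return path


def read_truth_table(path: str | Path) -> list[PlotTruth]:
    truths = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            corners = tuple((float(row[f"x{i}"]), float(row[f"y{i}"])) for i in range(4))
            truths.append(
                PlotTruth(
                    variant_index=int(row["variant"]),
                    block_index=int(row["block"]),
                    corner_coordinates=corners,
                    logistic_params=(float(row["A"]), float(row["B"]), float(row["C"])),
                )
            )
    return truths
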