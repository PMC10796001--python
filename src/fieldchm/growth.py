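"""Growth dynamics: relative growth rates and logistic curve fits.

Per plot, the median canopy height S(t) over the flight dates is reduced
to two complementary descriptions of growth:

* the relative growth rate between flights,
  RGR(t1, t2) = (ln S(t2) - ln S(t1)) / (t2 - t1)   [per day],
* a three-parameter logistic curve S(t) = A / (1 + exp(-B t - C)), where
  A is the asymptotic height (m), B the growth velocity (1/day) and C the
  onset offset (dimensionless; the inflection sits at t = -C/B).

Times are days since the first flight.  Fits use bounded nonlinear least
squares with a logit-transform initial guess and a few perturbed
restarts, keeping the best residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chm import PlotStats

__all__ = [
    "GrowthSeries",
    "LogisticFit",
    "RgrValue",
    "logistic",
    "relative_growth_rate",
    "fit_logistic",
    "fit_all",
    "parameter_grid",
    "series_from_stats",
]

A_MAX = 3.0  # m; cereal canopies stay well below this
B_MAX = 2.0  # 1/day


@dataclass(frozen=True)
class GrowthSeries:
    """Median canopy height of one plot over the flight dates."""

    variant_index: int
    block_index: int
    times: np.ndarray  # days, strictly increasing
    heights: np.ndarray  # metres, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if t.shape != h.shape or t.ndim != 1:
            raise ValueError("times and heights must be 1D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(h < 0):
            raise ValueError("heights must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class LogisticFit:
    variant_index: int
    block_index: int
    A: float
    B: float
    C: float
    rss: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class RgrValue:
    variant_index: int
    block_index: int
    t1: float
    t2: float
    rgr: float | None  # None when a height was non-positive


def logistic(t, A: float, B: float, C: float):
    """S(t) = A / (1 + exp(-B t - C)); S(-C/B) = A/2, S -> A as t -> inf for B > 0."""
    t = np.asarray(t, dtype=float)
    out = A / (1.0 + np.exp(-(B * t + C)))
    return out if out.ndim else float(out)


def relative_growth_rate(s1: float, s2: float, t1: float, t2: float) -> float:
    """(ln s2 - ln s1) / (t2 - t1), per day."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("RGR requires positive heights")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (np.log(s2) - np.log(s1)) / (t2 - t1)


def _initial_guess(t: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """A0 slightly above the observed maximum; B0, C0 from the log-linear
    regression of logit(S/A0) on t over interior points."""
    a0 = 1.05 * h.max()
    frac = np.clip(h / a0, 1e-6, 1.0 - 1e-6)
    logit = np.log(frac / (1.0 - frac))
    interior = (frac > 0.01) & (frac < 0.99)
    if interior.sum() >= 2:
        b0, c0 = np.polyfit(t[interior], logit[interior], 1)
    else:
        b0, c0 = np.polyfit(t, logit, 1)
    b0 = min(max(b0, 1e-3), B_MAX * 0.9)
    return a0, float(b0), float(c0)


def fit_logistic(series: GrowthSeries, n_restarts: int = 4, seed: int = 0) -> LogisticFit:
    """Bounded nonlinear least squares fit of the logistic curve.

    A in (0, 3] m and B in (0, 2] /day (growth, not decay); C unbounded.
    A multi-start strategy — the logit-transform guess plus ``n_restarts``
    log-normally perturbed copies — guards against local minima; the fit
    with the smallest residual sum of squares wins.  ``converged`` is
    False when every start fails or B sticks at its lower bound.
    """
    t, h = series.times, series.heights
    if t.size < 4:
        raise ValueError("logistic fit needs at least 4 time points")
    if np.all(h == 0):
        raise ValueError("all heights are zero: nothing to fit")

    a0, b0, c0 = _initial_guess(t, h)
    rng = np.random.default_rng(seed)
    starts = [(a0, b0, c0)]
    for _ in range(n_restarts):
        starts.append(
            (
                a0 * rng.lognormal(0.0, 0.2),
                b0 * rng.lognormal(0.0, 0.3),
                c0 + rng.normal(0.0, 1.0),
            )
        )

    def residuals(p):
        return logistic(t, *p) - h

    lb = [1e-9, 1e-6, -np.inf]
    ub = [A_MAX, B_MAX, np.inf]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(residuals, p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return LogisticFit(series.variant_index, series.block_index,
                           np.nan, np.nan, np.nan, np.inf, False, int(t.size))
    rss, res = best
    a, b, c = (float(v) for v in res.x)
    # a curve that is flat over the observed window (saturated or stalled
    # sigmoid) fits a constant series perfectly but is unidentifiable
    curve_range = abs(logistic(t[-1], a, b, c) - logistic(t[0], a, b, c))
    converged = bool(res.success) and b > 2e-6 and a > 0 and curve_range > 1e-6 * a
    return LogisticFit(series.variant_index, series.block_index, a, b, c, rss, converged, int(t.size))


def series_from_stats(stats: list[PlotStats]) -> list[GrowthSeries]:
    """Group per-plot median heights into one GrowthSeries per plot."""
    by_plot: dict[tuple[int, int], list[PlotStats]] = {}
    for s in stats:
        by_plot.setdefault((s.variant_index, s.block_index), []).append(s)
    out = []
    for (v, b), items in sorted(by_plot.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        items.sort(key=lambda s: s.time)
        out.append(
            GrowthSeries(
                variant_index=v,
                block_index=b,
                times=np.array([s.time for s in items]),
                heights=np.array([s.median for s in items]),
            )
        )
    return out


def fit_all(
    stats: list[PlotStats], n_restarts: int = 4, seed: int = 0
) -> tuple[list[LogisticFit], list[RgrValue]]:
    """Fit every plot and compute RGR for every consecutive flight pair.

    A failed fit or a non-positive height never aborts the batch: the fit
    is recorded with ``converged=False`` and the RGR as None.
    """
    if not stats:
        raise ValueError("no plot statistics supplied")
    series = series_from_stats(stats)
    grids = {tuple(s.times) for s in series}
    if len(grids) != 1:
        raise ValueError("plots do not share a common time grid")
    fits, rgrs = [], []
    for s in series:
        try:
            fits.append(fit_logistic(s, n_restarts=n_restarts, seed=seed))
        except ValueError:
            fits.append(
                LogisticFit(s.variant_index, s.block_index,
                            np.nan, np.nan, np.nan, np.inf, False, int(s.times.size))
            )
        for k in range(s.times.size - 1):
            h1, h2 = s.heights[k], s.heights[k + 1]
            t1, t2 = float(s.times[k]), float(s.times[k + 1])
            value = (
                relative_growth_rate(h1, h2, t1, t2) if h1 > 0 and h2 > 0 else None
            )
            rgrs.append(RgrValue(s.variant_index, s.block_index, t1, t2, value))
    return fits, rgrs


def parameter_grid(
    fits: list[LogisticFit],
    seg=None,
    parameter: str = "A",
    n_blocks: int | None = None,
    plots_per_block: int | None = None,
) -> np.ndarray:
    """Arrange one fitted parameter into a (blocks x variants) grid for
    heat-map display; missing or failed fits appear as NaN.

    The layout comes either from a PlotSegmentation (``seg``) or from
    explicit ``n_blocks`` / ``plots_per_block`` counts; every fit must fall
    inside it.
    """
    if parameter not in ("A", "B", "C"):
        raise ValueError("parameter must be 'A', 'B' or 'C'")
    if seg is not None:
        n_blocks = max(p.block_index for p in seg.plots)
        plots_per_block = max(p.variant_index for p in seg.plots)
        seg_keys = {(p.variant_index, p.block_index) for p in seg.plots}
        fit_keys = {(f.variant_index, f.block_index) for f in fits}
        if not fit_keys <= seg_keys:
            raise ValueError("fits reference plots absent from the segmentation")
    if n_blocks is None or plots_per_block is None:
        raise ValueError("provide either seg or n_blocks and plots_per_block")
    grid = np.full((n_blocks, plots_per_block), np.nan)
    for f in fits:
        b, v = f.block_index - 1, f.variant_index - 1
        if not (0 <= b < n_blocks and 0 <= v < plots_per_block):
            raise ValueError(f"fit ({f.variant_index}, {f.block_index}) outside the layout")
        grid[b, v] = getattr(f, parameter)
    return grid


def render_heatmap(grid: np.ndarray, path, parameter: str = "A") -> None:
    """Save a colour-coded (blocks x variants) parameter map as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, grid.shape[1] * 0.25), 2 + grid.shape[0]))
    im = ax.imshow(grid, aspect="auto", cmap="viridis")
    ax.set_xlabel("variant")
    ax.set_ylabel("block")
    ax.set_yticks(range(grid.shape[0]), [str(b + 1) for b in range(grid.shape[0])])
    fig.colorbar(im, ax=ax, label=parameter)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def fits_to_frame(fits: list[LogisticFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": f.variant_index,
                "block": f.block_index,
                "A": f.A,
                "B": f.B,
                "C": f.C,
                "rss": f.rss,
                "converged": f.converged,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def rgr_to_frame(rgrs: list[RgrValue]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant_index,
                "block": r.block_index,
                "t1": r.t1,
                "t2": r.t2,
                "rgr": np.nan if r.rgr is None else r.rgr,
            }
            for r in rgrs
        ]
    )
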