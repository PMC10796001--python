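# Methods

## Processing model

The pipeline treats a LiDAR flight as a sample of a 2.5D surface: the
terrain where the ground is bare, the canopy top inside sown plots. All
flights share one projected metric frame, so rasterizing every flight
over the bounding box of the first flight puts them on a common pixel
grid and makes per-pixel arithmetic across dates meaningful. Crop height
is defined relative to the first flight: that flight is assumed to
precede emergence, so its (imputed, unfiltered) raster is the digital
elevation model (DEM) of the bare ground. For any later flight the crop
height model is

    CHM_t = maxfilter(R_t, w) − DEM,  clamped below at 0,

where `R_t` is the imputed raster of flight t and `maxfilter` is a
morphological dilation with a `w × w` window. The dilation fills the
gaps between individual canopy returns ("covering the surface with a
deformable blanket"); the DEM is deliberately **not** max-filtered, as
dilating ground elevations would only inflate the reference surface and
bias heights downward. A `max_filter_dem` switch exists for users who
prefer symmetric treatment.

## Stage-by-stage choices

**Outlier filter.** "Central 99.9 %" is implemented two-sided per axis:
a point survives when each coordinate lies within the
[(1−m)/2, 1−(1−m)/2] empirical quantile interval, m = 0.999 by default.
Spurious LiDAR returns occur above the canopy (birds, dust) and below
the ground (multipath), so symmetric trimming is the appropriate
reading of a quantile cutoff.

**Rasterization.** Pixel (r, c) covers the half-open square
[x_min + c·p, x_min + (c+1)·p) × (y_max − (r+1)·p, y_max − r·p]; row 0
is the northernmost row (standard image orientation). Points on the
east/north boundary of the grid are clipped into the last pixel so that
every point is assigned to exactly one pixel. The default pixel size of
0.05 m resolves a 1.2 m plot into 24 columns while keeping the raster of
a 3-block trial below ~1.2 M pixels. At 200 points/m² roughly half the
0.05 m pixels receive no point; the median imputation (below) is an
integral part of the method, not an edge case.

**Median imputation.** Each pass replaces every missing pixel that has
at least one defined neighbour in its window (default 3 × 3) by the
median of the defined values there; defined pixels never change. Passes
repeat until closure. Iterating to closure, rather than one pass, is
required because the empty-pixel pattern at realistic densities contains
clumps larger than one window.

**Quantization and storage.** Elevations are mapped to 16-bit levels,
`level = round((z − z_min)/z_scale)` with
`z_scale = (z_max − z_min)/65535`, so a 10 m elevation range quantizes
at ~0.08 mm — far below sensor noise. When a raster still has missing
pixels one level is held back (`range/65534`) and the PNG stores defined
data shifted up by one with level 0 reserved for "missing"; the shift
and the reserved level live in the JSON sidecar, making the round trip
bit-exact. A constant raster stores z_scale = 1 and all-zero levels.

**Region of interest.** Rotation/crop is configuration, not an
interactive step, so runs are reproducible headless. Rotation by
multiples of 90° is exact (array rotation); other angles use bilinear
interpolation and mark pixels that sample outside the original grid as
missing. The same ROI applies to every flight through the shared frame.

**Segmentation.** Operates on the *height difference* between a
reference flight and the first flight, which cancels the terrain and
leaves plots as plateaus on a flat background. The reference defaults to
the last flight — at the first flight the crop has not emerged and there
is, by construction, nothing to segment. Summed-profile edges: the
per-column (or per-row) means are min–max normalized, differenced once,
and peaks of the derivative with prominence ≥ 0.1 (of the normalized
range) and a minimum same-sign separation (default: half the expected
plot pitch in pixels) are taken as edges; a rising peak at i starts a
plot at i+1, the next falling peak at j ends it at j+1. Rectangles are
the outer product of block row-intervals and per-block column-intervals,
indexed row-major: block 1 is the northernmost, variant 1 the leftmost.
When expected counts are configured, any disagreement raises an error
naming both counts rather than silently mis-labelling plots.

**Skew rectification.** Sowing drift shifts plot columns laterally along
the plot length, turning rectangles into parallelograms with a common
shear per block. The shear is estimated by maximizing the sharpness
(sum of squared first differences) of the column profile recomputed
after shearing rows — a 41-point grid scan over ±0.2 refined by bounded
scalar minimization — and undone with a per-row horizontal shift using
linear interpolation. One shear per block (not per plot) matches the
drift mechanism and keeps the warp rigid. Note the sign convention:
image rows increase southward, so the image-space shear is the negative
of the field-space lateral drift per metre.

**Plot statistics.** Computed over each rectangle inset by a 2-pixel
margin (0.1 m at default resolution) to drop mixed plot/alley edge
pixels. Quantiles (default 0.1, 0.25, 0.75, 0.9 plus the median) use
linear interpolation between order statistics.

**Growth models.** Times are days since the first flight; B and C are
reported in that convention (inflection day = −C/B). The logistic fit
is bounded nonlinear least squares (trust-region reflective) with
A ∈ (0, 3 m] — cereals cannot exceed 3 m — and B ∈ (0, 2/day] enforcing
growth rather than decay; C is free. Initialization: A₀ = 1.05 × max
height; B₀ and C₀ from the straight-line fit of logit(S/A₀) against t
on interior points; four log-normally perturbed restarts guard against
local minima and the best RSS wins (adding restarts can therefore never
worsen the fit). A fit whose curve is flat over the observed window — a
saturated or stalled sigmoid, which reproduces a constant series
perfectly but is unidentifiable — is flagged `converged = False`, as is
B stuck at its lower bound. RGR uses the median height, and a
non-positive height yields a missing RGR for that interval without
aborting the batch. The curve model is pluggable (any callable of
(t, A, B, C) shape could replace the logistic in `fit_logistic`'s
residual), but only the logistic is implemented.

## The synthetic trial

The generator emulates the study conditions the pipeline targets:
3 blocks × 48 plots of 1.2 × 9 m separated by 0.6 m alleys with a 2 m
bare border; terrain as a sum of two orthogonal sinusoids (amplitude
0.2 m peak-to-peak, 30 m wavelength) — the simplest smooth stand-in for
gentle field topography; uniform random points at 200/m² (LiDAR scan
lines homogenized over a flight); Gaussian elevation noise of 0.03 m;
seven flights at days 0–90 in 15-day steps, spanning an April-to-June
growing season from pre-emergence to maturity. Per plot the canopy is a
solid top surface at terrain + S(t) with logistic S; A varies smoothly
across the field (≈ 0.68–0.98 m) with small per-plot jitter so parameter
maps have recoverable spatial structure, B ≈ 0.15/day, C ≈ −6
(inflection near day 40). Skew, when enabled, shears plot footprints
only; the terrain stays axis-aligned, isolating the rectification stage.

What the simulator does **not** model: beam divergence and footprint,
multiple returns and partial canopy penetration, occlusion, scan-line
density banding, registration error between flights, lodging and
weather damage. Passing tests therefore demonstrate the correctness of
the image-processing and model-fitting chain under realistic geometry,
density and noise — not robustness to every LiDAR artefact of a real
campaign.

With these conditions the full pipeline recovers per-plot median height
with an RMSD of ~2.6 cm over all 144 × 7 plot-times (the acceptance
script recomputes this), about half of it a systematic +2–3 cm offset:
the 3 × 3 maximum filter takes the largest of ~5–9 noisy pixel values
inside each window, i.e. an order-statistic bias of roughly
1σ ≈ 0.03 m scaled down by pixel averaging. On real data the same
mechanism rides on top of canopy-penetration effects that push the other
way; the filter window trades these off and is therefore configurable.

## Numerical and degenerate-input conventions

- Rasters compare georeference exactly (same origin, pixel size) before
  any cross-date arithmetic; a mismatch is an error, never a resample.
- `quantize` of an already-quantized raster, imputation of an all-missing
  raster, fitting fewer than 4 points or an all-zero series, margins
  that collapse a rectangle, crops outside bounds and non-increasing
  flight dates are all rejected with specific errors.
- Edge detection requires a strictly non-constant profile; a flat image
  reports "no edges" instead of fabricating a segmentation.
- All stochastic components (generator, fit restarts) run off explicit
  integer seeds; identical inputs and seeds give bit-identical outputs.

## Problem sizes used in the test-bench

The shared test fixture uses a 3 × 12-plot trial at the full design
density and noise (the per-plot mechanics are identical to the 48-plot
layout; only the column count shrinks), while the height-recovery and
segmentation checks run the full 3 × 48-plot, seven-flight trial. The
grid-search oracle for the logistic fit uses a 81 × 41 × 61 parameter
lattice around the true values, evaluated exhaustively on the same
replicates as the least-squares fit.
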