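# fieldchm

Fast, fully automatic extraction of per-plot crop height and growth
dynamics from UAV-LiDAR point clouds of field-plot trials.

Agronomic experiments are sown as arrays of small rectangular plots
(here ~1.2 × 9 m) grouped into blocks. A drone-mounted LiDAR scans the
trial repeatedly during the season, giving one georeferenced point cloud
per flight. `fieldchm` turns those clouds into per-plot growth traits
without any manual digitizing:

1. **Filter** — returns outside the central 99.9 % of the empirical x, y
   or z distribution are discarded.
2. **Rasterize** — points are binned onto a uniform grid (default
   0.05 m); each pixel is the mean z of its points; empty pixels are
   imputed by an iterated neighbourhood median filter. Rasters are
   stored as compact 16-bit PNGs with a JSON sidecar (georeference +
   quantization), at sub-millimetre round-trip error.
3. **Segment** — plot edges appear as peaks in the first difference of
   the image's column/row sums; blocks and plots are recovered as
   axis-aligned rectangles. Sowing drift that skews plots into
   parallelograms is estimated as a per-block shear (the one that
   maximizes profile sharpness) and undone by an affine warp.
4. **Crop height model (CHM)** — a morphological maximum filter (a
   "deformable blanket" over the noisy surface) traces the canopy top;
   the bare-ground elevation of the first, pre-emergence flight (DEM) is
   subtracted: CHM = max-filter(DSM_t) − DEM, clamped at 0.
5. **Growth traits** — per plot and flight: mean, sd, median, min, max
   and quantiles of the CHM. Per plot over time, with S(t) the median
   height at day t:
   - relative growth rate `RGR(t1, t2) = (ln S(t2) − ln S(t1)) / (t2 − t1)`,
   - a logistic fit `S(t) = A / (1 + exp(−B·t − C))` by bounded
     nonlinear least squares, where A is the mature canopy height (m),
     B the growth velocity (1/day) and C the onset offset (inflection
     at t = −C/B days).

A built-in simulator (`fieldchm.synthetic`) generates multi-flight
clouds of a trial with fully known ground truth — undulating terrain,
blocks of plots with logistic height trajectories, sowing skew, point
density and elevation noise — so every stage is testable end to end
without field data.

## Worked example

```python
import fieldchm as fc

design = fc.FieldDesign(n_blocks=1, plots_per_block=6, seed=4)
times = [0.0, 45.0, 90.0]
clouds, truth = fc.generate_field(design, times)
result = fc.process_clouds(clouds, times, expected_blocks=1,
                           expected_plots_per_block=6, min_separation_px=18)
for s in result.stats:
    if s.time == 90.0:
        print(s.variant_index, round(s.median, 3))
```

Running `python examples/height_statistics.py` (the script version of
the above) prints:

```
variant  median   mean     sd      q10    q90   (m, day 90)
    1    0.796   0.796  0.030   0.759  0.833
    2    0.895   0.896  0.029   0.862  0.932
    3    0.817   0.817  0.029   0.780  0.854
    4    0.705   0.706  0.030   0.667  0.744
    5    0.652   0.654  0.028   0.619  0.689
    6    0.765   0.766  0.030   0.729  0.804
largest |median - true height| across plots: 2.6 cm
```

Each row is one plot's canopy-height distribution at day 90: the median
tracks the plot's true (simulated) height to a few centimetres, and the
spread reflects LiDAR noise plus surface texture. The other scripts in
`examples/` walk through simulation, rasterization, segmentation/skew
rectification, growth-curve fitting and the config-driven run.

A thin CLI mirrors the library:

```
fieldchm simulate --out sim/ --seed 1
fieldchm rasterize --input sim/cloud_t0.xyz --pixel-size 0.05 --out t0.png
fieldchm run --config run.yaml
```

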