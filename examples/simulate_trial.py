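"""Simulate a multi-flight LiDAR scan of a field trial with known truth.

Builds a small 2-block trial, writes one XYZ cloud per flight plus the
ground-truth table, and prints what the generator produced.
"""

from pathlib import Path

import fieldchm as fc

out = Path("scratch_example_sim")
out.mkdir(exist_ok=True)

design = fc.FieldDesign(n_blocks=2, plots_per_block=8, noise_sd_m=0.03,
                        point_density_per_m2=200.0, seed=1)
times = [0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0]
clouds, truth = fc.generate_field(design, times)

for i, cloud in enumerate(clouds):
    fc.write_xyz(cloud, out / f"cloud_t{i}.xyz")
fc.write_truth_table(truth, out / "truth.csv")

tr = truth[0]
print(f"{len(clouds)} flights, {len(clouds[0])} points each, "
      f"{len(truth)} plots of {design.plot_width_m} x {design.plot_length_m} m")
print(f"plot (variant 1, block 1): A={tr.logistic_params[0]:.3f} m, "
      f"B={tr.logistic_params[1]:.3f} /day, C={tr.logistic_params[2]:.2f}")
print(f"its true canopy height at day 90: {tr.height_at(90.0):.3f} m")
# A is the mature canopy height each plot approaches; B the growth speed;
# C places the growth onset on the time axis (inflection at t = -C/B days).
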