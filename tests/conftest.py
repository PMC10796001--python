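import numpy as np
import pytest

import fieldchm as fc

FLIGHT_DAYS = [0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0]


@pytest.fixture(scope="session")
def flight_days():
    return list(FLIGHT_DAYS)


@pytest.fixture(scope="session")
def small_field(flight_days):
    """A 3-block x 12-plot trial with realistic noise, run end to end once
    and shared across tests that need a segmented, fitted result."""
    design = fc.FieldDesign(
        n_blocks=3, plots_per_block=12, noise_sd_m=0.03,
        point_density_per_m2=200.0, seed=11,
    )
    clouds, truth = fc.generate_field(design, flight_days)
    result = fc.process_clouds(
        clouds, flight_days,
        expected_blocks=3, expected_plots_per_block=12, min_separation_px=18,
    )
    return design, truth, result


@pytest.fixture(scope="session")
def clean_block():
    """A single noise-free block on flat terrain: the easiest possible
    segmentation input, with exact plateau heights."""
    design = fc.FieldDesign(
        n_blocks=1, plots_per_block=8, noise_sd_m=0.0, terrain_amplitude_m=0.0,
        point_density_per_m2=300.0, seed=5,
    )
    clouds, truth = fc.generate_field(design, [0.0, 60.0])
    return design, truth, clouds


def rasterize_pair(clouds, pixel_size=0.05, window=3):
    """Impute both flights of a two-flight set onto the first flight's grid."""
    f0 = fc.filter_outliers(clouds[0])
    pts = f0.points
    bounds = (
        float(pts[:, 0].min()), float(pts[:, 0].max()),
        float(pts[:, 1].min()), float(pts[:, 1].max()),
    )
    out = []
    for c in clouds:
        r = fc.rasterize(fc.filter_outliers(c), pixel_size, bounds=bounds)
        r, _ = fc.impute_missing(r, window)
        out.append(r)
    return out
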