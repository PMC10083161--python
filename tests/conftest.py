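"""Shared fixtures: tiny hand-built tables and seeded synthetic studies."""

import numpy as np
import pandas as pd
import pytest

from gwtrend import (
    SyntheticConfig, assign_panels, center_by_station, generate_network,
    simulate_observations, true_coefficients, two_region_surface,
)
from gwtrend.table import ObservationTable, ScaleState


@pytest.fixture
def tiny_log10_table():
    """10 stations x 3 visits on a 100 km square, log10 scale."""
    rng = np.random.default_rng(42)
    n_st = 10
    df = pd.DataFrame({
        "station_id": np.repeat([f"A{i}" for i in range(n_st)], 3),
        "x": np.repeat(rng.uniform(0, 100_000, n_st), 3),
        "y": np.repeat(rng.uniform(0, 100_000, n_st), 3),
        "year": np.tile([2008, 2014, 2020], n_st),
        "value": rng.normal(1.0, 0.2, 3 * n_st),
    })
    return ObservationTable(df, ScaleState.LOG10)


@pytest.fixture
def tiny_centered_table(tiny_log10_table):
    return center_by_station(tiny_log10_table)


def make_two_region_study(seed, n_stations=800, noise_sd=0.1, **config_kwargs):
    """Simulate the default study: two-region slope field, rotating panels.

    Returns (centered_table, stations, truth, config, surface).
    """
    config = SyntheticConfig(
        n_stations=n_stations, noise_sd_log10=noise_sd, seed=seed, **config_kwargs
    )
    surface = two_region_surface(config.bounds)
    stations = generate_network(config)
    schedule = assign_panels(stations, config)
    table = simulate_observations(schedule, stations, surface, config)
    truth = true_coefficients(stations, surface)
    return center_by_station(table), stations, truth, config, surface


@pytest.fixture(scope="session")
def two_region_small():
    """300-station two-region study used by several unit tests."""
    return make_two_region_study(seed=11, n_stations=300)
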