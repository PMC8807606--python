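import numpy as np
import pytest

from vegclim import local_signal, synthetic_data
from vegclim.grid_core import GridGeometry


def span_geometry(nlat: int, nlon: int) -> GridGeometry:
    """Small grid spanning 60S-80N, global in longitude."""
    dlat = 140.0 / nlat
    dlon = 360.0 / nlon
    lat = -60.0 + dlat / 2.0 + dlat * np.arange(nlat)
    lon = -180.0 + dlon / 2.0 + dlon * np.arange(nlon)
    return GridGeometry(lat=lat, lon=lon)


@pytest.fixture(scope="session")
def tiny_baseline():
    """Fast 12x24, 6-year noise-free baseline with its decomposition."""
    cfg = synthetic_data.BaselineSyntheticConfig(
        geometry=span_geometry(12, 24),
        years=tuple(range(2003, 2009)),
        obs_noise_sd=0.0,
        seed=7,
    )
    fields, truth = synthetic_data.generate_baseline_obs(cfg)
    records = local_signal.decompose(fields, radius_km=truth.radius_km)
    samples = local_signal.build_sensitivity_samples(records)
    return cfg, fields, truth, records, samples


@pytest.fixture(scope="session")
def default_noise_free_baseline():
    """The full default 60x120, 12-year noise-free baseline (shared by the
    recovery and coefficient-recovery acceptance tests)."""
    cfg = synthetic_data.BaselineSyntheticConfig(obs_noise_sd=0.0, seed=0)
    fields, truth = synthetic_data.generate_baseline_obs(cfg)
    records = local_signal.decompose(fields, radius_km=truth.radius_km)
    samples = local_signal.build_sensitivity_samples(records)
    return cfg, fields, truth, records, samples


@pytest.fixture(scope="session")
def small_scenario_ensemble():
    """3-model, 5-yearly scenario ensemble for projection tests."""
    cfg = synthetic_data.ScenarioSyntheticConfig(
        n_models=3, years=tuple(range(2015, 2101, 5)), seed=11
    )
    runs, truth = synthetic_data.generate_scenario_ensemble(cfg)
    return cfg, runs, truth
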