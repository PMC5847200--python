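import numpy as np
import pandas as pd
import pytest

from swiftascent import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_weather(default_config):
    return synthetic.simulate_weather_grid(default_config)


@pytest.fixture(scope="session")
def full_year(default_config, default_weather):
    """One full simulated annual cycle at default study conditions."""
    return synthetic.simulate_annual_cycle(default_config, "bird01", "alps", weather=default_weather)


def winter_config(**overrides):
    """A non-breeding-season-only configuration (token one-day shoulder
    phases), used where a single stationary tropical regime is wanted."""
    base = dict(
        start="2014-11-01", end="2015-02-28",
        breeding_end="2014-11-02", autumn_migration_end="2014-11-03",
        nonbreeding_end="2015-02-26", spring_migration_end="2015-02-27",
        seed=5,
    )
    base.update(overrides)
    return synthetic.SimulationConfig(**base)


@pytest.fixture(scope="session")
def winter_sim():
    cfg = winter_config()
    grid = synthetic.simulate_weather_grid(cfg)
    series, truth = synthetic.simulate_annual_cycle(cfg, "w01", "pop", weather=grid)
    return cfg, grid, series, truth


def match_truth(frame: pd.DataFrame, truth_twilights: pd.DataFrame, tolerance="2h"):
    """Nearest-time join of per-event pipeline output onto generator truth."""
    left = frame.sort_values("event_time").reset_index(drop=True)
    right = truth_twilights.sort_values("event_time").reset_index(drop=True)
    out = pd.merge_asof(
        left, right, on="event_time", direction="nearest",
        tolerance=pd.Timedelta(tolerance), suffixes=("", "_true"),
    )
    return out.dropna(subset=[c for c in ("lat_true", "phase_true", "ascent") if c in out.columns])
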