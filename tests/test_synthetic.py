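import numpy as np
import pandas as pd
import pytest

from conftest import winter_config
from swiftascent import altimetry, synthetic


def test_same_seed_bit_identical_different_seed_differs():
    cfg = winter_config(end="2014-11-20", nonbreeding_end="2014-11-18", spring_migration_end="2014-11-19")
    grid = synthetic.simulate_weather_grid(cfg)
    s1, t1 = synthetic.simulate_annual_cycle(cfg, "a", "p", weather=grid)
    s2, t2 = synthetic.simulate_annual_cycle(cfg, "a", "p", weather=grid)
    assert (s1.light == s2.light).all() and (s1.pressure == s2.pressure).all()
    assert t1.twilights.equals(t2.twilights)
    cfg3 = winter_config(seed=99, end="2014-11-20", nonbreeding_end="2014-11-18",
                         spring_migration_end="2014-11-19")
    s3, _ = synthetic.simulate_annual_cycle(cfg3, "a", "p", weather=grid)
    assert not (s1.light == s3.light).all()


def test_zero_ascent_probability_yields_no_ascents():
    cfg = winter_config(
        end="2014-12-05", nonbreeding_end="2014-12-03", spring_migration_end="2014-12-04",
        dawn_ascent_p={"breeding": 0.0, "migration": 0.0, "non-breeding": 0.0},
    )
    _, truth = synthetic.simulate_annual_cycle(cfg)
    assert not truth.twilights["ascent"].any()


def test_degenerate_height_distribution():
    cfg = winter_config(
        end="2014-12-05", nonbreeding_end="2014-12-03", spring_migration_end="2014-12-04",
        dawn_ascent_p={"breeding": 0.0, "migration": 0.0, "non-breeding": 1.0},
        ascent_height_mean_m=400.0, ascent_height_sd_m=0.0,
    )
    _, truth = synthetic.simulate_annual_cycle(cfg)
    nb_dawn = truth.twilights.query("phase == 'non-breeding' and kind == 'dawn'")
    assert nb_dawn["ascent"].all()
    assert (nb_dawn["ascent_height_m"] == 400.0).all()


def test_ascent_rates_match_configured_probabilities(full_year, default_config):
    """Empirical per-phase dawn/dusk ascent frequencies over the year stay
    within ~3 binomial standard errors of the configured probabilities."""
    _, truth = full_year
    cfg = default_config
    for (phase, kind), grp in truth.twilights.groupby(["phase", "kind"]):
        p = cfg.dawn_ascent_p[phase] if kind == "dawn" else cfg.dusk_ascent_p(phase)
        n = len(grp)
        se = np.sqrt(max(p * (1 - p), 1e-9) / n)
        assert abs(grp["ascent"].mean() - p) < 3.5 * se + 1e-9, (phase, kind)


def test_dusk_probability_is_half_the_dawn_odds(default_config):
    p_dawn = default_config.dawn_ascent_p["non-breeding"]
    p_dusk = default_config.dusk_ascent_p("non-breeding")
    odds = lambda p: p / (1 - p)
    assert odds(p_dusk) == pytest.approx(0.5 * odds(p_dawn))


def test_pressure_inverts_to_true_altitude_without_noise():
    cfg = synthetic.noise_free(winter_config(end="2014-11-20", nonbreeding_end="2014-11-18",
                                             spring_migration_end="2014-11-19"))
    grid = synthetic.simulate_weather_grid(cfg)
    series, truth = synthetic.simulate_annual_cycle(cfg, "nf", "p", weather=grid)
    pres = series.pressure
    pos = truth.position.reindex(pres.index)
    p0 = synthetic.grid_lookup(grid, "mslp", pos["lat"].to_numpy(), pos["lon"].to_numpy(), pres.index)
    recovered = altimetry.pressure_to_altitude(pres.to_numpy(), p0)
    np.testing.assert_allclose(recovered, truth.altitude.reindex(pres.index).to_numpy(), atol=1.0)


def test_light_monotone_in_solar_elevation_without_noise():
    from swiftascent.solar import solar_elevation

    cfg = synthetic.noise_free(winter_config(end="2014-11-10", nonbreeding_end="2014-11-08",
                                             spring_migration_end="2014-11-09",
                                             cavity_attendance_p=0.0))
    grid = synthetic.simulate_weather_grid(cfg)
    series, truth = synthetic.simulate_annual_cycle(cfg, "nf", "p", weather=grid)
    elev = solar_elevation(truth.position["lat"], truth.position["lon"], series.light.index)
    order = np.argsort(elev)
    light_sorted = series.light.to_numpy()[order]
    assert (np.diff(light_sorted) >= -1e-9).all()


def test_weather_grid_spacing_and_span(default_weather, default_config):
    wc = default_config.weather
    lats = default_weather["lat"].to_numpy()
    lons = default_weather["lon"].to_numpy()
    assert lats[0] == wc.lat_min and lats[-1] == wc.lat_max
    np.testing.assert_allclose(np.diff(lats), wc.resolution_deg)
    np.testing.assert_allclose(np.diff(lons), wc.resolution_deg)
    times = pd.DatetimeIndex(default_weather["time"].to_numpy())
    assert ((times[1:] - times[:-1]) == pd.Timedelta(hours=6)).all()


def test_zero_front_amplitude_means_zero_pressure_deltas():
    import dataclasses

    cfg = winter_config(end="2014-11-20", nonbreeding_end="2014-11-18", spring_migration_end="2014-11-19")
    cfg = dataclasses.replace(cfg, weather=synthetic.WeatherConfig(front_amplitude_hpa=0.0))
    grid = synthetic.simulate_weather_grid(cfg)
    mslp = grid["mslp"].to_numpy()
    # 24 h = 4 six-hour steps; with no fronts the field is constant in time
    assert np.abs(mslp[4:] - mslp[:-4]).max() == 0.0


def test_single_front_delta_peaks_at_crossing():
    cfg = winter_config(end="2014-12-05", nonbreeding_end="2014-12-03", spring_migration_end="2014-12-04")
    front = synthetic.Front(
        t0=pd.Timestamp("2014-11-10"), center_lat=45.0, start_lon=-41.0,
        speed_deg_per_day=12.0, width_deg=8.0, amplitude_hpa=15.0,
    )
    grid = synthetic.simulate_weather_grid(cfg, fronts=[front])
    # fixed point at the front's latitude; crossing when center_lon == point lon
    point_lon = 8.0
    crossing = front.t0 + pd.Timedelta(days=(point_lon - front.start_lon) / front.speed_deg_per_day)
    mslp = grid["mslp"].sel(lat=45.0, lon=7.5)
    times = pd.DatetimeIndex(grid["time"].to_numpy())
    d24 = np.abs(mslp.to_numpy()[4:] - mslp.to_numpy()[:-4])
    t_peak = times[4:][np.argmax(d24)]
    assert abs((t_peak - crossing) / pd.Timedelta(days=1)) < 1.5


def test_invalid_config_rejected():
    with pytest.raises(synthetic.ConfigError):
        synthetic.SimulationConfig(dawn_ascent_p={"breeding": 1.5, "migration": 0.2, "non-breeding": 0.2})
    with pytest.raises(synthetic.ConfigError):
        synthetic.SimulationConfig(breeding_end="2016-01-01")
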