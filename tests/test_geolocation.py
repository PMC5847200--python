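import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import match_truth, winter_config
from swiftascent import geolocation as geo
from swiftascent import synthetic


def _winter_bird(**overrides):
    cfg = winter_config(**overrides)
    grid = synthetic.simulate_weather_grid(cfg)
    series, truth = synthetic.simulate_annual_cycle(cfg, "g01", "pop", weather=grid)
    return cfg, series, truth


# ---- twilight detection ----

def test_detected_dawn_matches_true_sun_crossing():
    cfg, series, truth = _winter_bird(end="2014-11-20", nonbreeding_end="2014-11-18",
                                      spring_migration_end="2014-11-19", cavity_attendance_p=0.0)
    nf = synthetic.noise_free(cfg)
    grid = synthetic.simulate_weather_grid(nf)
    series, truth = synthetic.simulate_annual_cycle(nf, "g01", "pop", weather=grid)
    events = geo.detect_twilights(series.light, nf.light_max / 2)
    assert len(events) > 30
    tt = truth.twilights.sort_values("event_time")["event_time"].to_numpy()
    offsets = []
    for e in events:
        i = np.argmin(np.abs(tt - np.datetime64(e.timestamp)))
        offsets.append(abs((e.timestamp - pd.Timestamp(tt[i])).total_seconds()) / 60)
    # shoulder-day events (the one-day transit to the winter site) can match
    # against a twilight computed for a distant waypoint; the bulk must be
    # within a sampling interval of truth
    assert np.median(offsets) < 2.0
    assert np.quantile(offsets, 0.9) < 5.0


def test_light_always_below_threshold_warns_and_returns_empty():
    t5 = pd.date_range("2014-11-01", periods=600, freq="5min")
    with pytest.warns(UserWarning):
        events = geo.detect_twilights(pd.Series(1.0, index=t5), threshold=32.0)
    assert events == []


def test_threshold_tie_assigned_to_interval_start():
    t5 = pd.date_range("2014-11-01", periods=200, freq="5min")
    light = pd.Series(0.0, index=t5)
    light.iloc[50] = 32.0  # exactly at threshold: still night
    light.iloc[51:140] = 64.0
    events = geo.detect_twilights(light, 32.0, min_day_duration=pd.Timedelta(hours=2))
    dawn = [e for e in events if e.kind == "dawn"][0]
    assert dawn.timestamp == t5[50]  # crossing starts at the threshold sample


def test_flag_unnatural_step_rules():
    t5 = pd.date_range("2014-11-01", periods=48, freq="5min")
    ev = geo.TwilightEvent(t5[24], "dawn")
    smooth = pd.Series(np.linspace(0, 64, 48), index=t5)
    cavity = smooth.copy()
    cavity.iloc[:24] = 0.0
    cavity.iloc[24:] = 64.0
    exact = smooth.copy()
    exact.iloc[:24] = 0.0
    exact.iloc[24:] = 0.8 * 64  # exactly the threshold fraction: inclusive
    assert geo.flag_unnatural(smooth, [ev], dynamic_range=64.0)[0].natural
    assert not geo.flag_unnatural(cavity, [ev], dynamic_range=64.0)[0].natural
    assert not geo.flag_unnatural(exact, [ev], dynamic_range=64.0)[0].natural


def test_breeding_cavity_twilights_are_flagged_unnatural(full_year, default_config):
    series, truth = full_year
    events = geo.detect_twilights(series.light, default_config.light_max / 2)
    events = geo.flag_unnatural(series.light, events, dynamic_range=default_config.light_max)
    df = pd.DataFrame({"event_time": [e.timestamp for e in events],
                       "natural": [e.natural for e in events]})
    m = match_truth(df, truth.twilights.rename(columns={"phase": "phase_true"}))
    unnatural_rate = 1 - m.groupby("phase_true")["natural"].mean()
    assert unnatural_rate["breeding"] > 0.7  # cavity attendance dominates
    assert unnatural_rate["non-breeding"] < 0.1


# ---- grid HMM ----

def test_forward_backward_equals_path_enumeration():
    rng = np.random.default_rng(42)
    K, T = 4, 3
    em = rng.uniform(0.05, 1.0, (T, K))
    M = rng.uniform(0.05, 1.0, (K, K))
    M /= M.sum(axis=1, keepdims=True)
    post = geo.forward_backward(em, M)
    brute = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = em[0][path[0]] / K
        for t in range(1, T):
            p *= M[path[t - 1], path[t]] * em[t][path[t]]
        for t in range(T):
            brute[t, path[t]] += p
    brute /= brute.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(post, brute, atol=1e-9)


def test_posterior_normalisation_and_flat_likelihood():
    grid = geo.GridSpec(0, 4, 0, 4, 1.0)
    K = len(grid.lats) * len(grid.lons)
    flat = [np.ones((len(grid.lats), len(grid.lons))) for _ in range(3)]
    post = geo.forward_backward(flat, lambda v: v)
    for t in range(3):
        assert post[t].sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(post[t], 1.0 / K)


def test_stationary_bird_posterior_median_near_truth():
    cfg = synthetic.noise_free(winter_config(end="2014-11-22", nonbreeding_end="2014-11-20",
                                             spring_migration_end="2014-11-21",
                                             cavity_attendance_p=0.0))
    grid = synthetic.simulate_weather_grid(cfg)
    series, truth = synthetic.simulate_annual_cycle(cfg, "s01", "pop", weather=grid)
    events = geo.detect_twilights(series.light, cfg.light_max / 2)
    events = geo.flag_unnatural(series.light, events, dynamic_range=cfg.light_max)
    posts = geo.estimate_positions(events, movement_sd_deg=0.5, twilight_sd_minutes=2.0,
                                   threshold_elevation_deg=cfg.light_center_deg)
    # skip the shoulder days (colony, transit, departure); truth is the winter site
    site = (cfg.nonbreeding_lat, cfg.nonbreeding_lon)
    errs = []
    for p in posts[6:-6]:
        lat, lon = p.median_position()
        errs.append(max(abs(lat - site[0]), abs(lon - site[1])))
    assert np.median(errs) <= 1.0  # within one grid cell


def test_migratory_track_recovered_within_two_cells(default_config, default_weather):
    series, truth = synthetic.simulate_annual_cycle(default_config, "m01", "pop", weather=default_weather)
    events = geo.detect_twilights(series.light, default_config.light_max / 2)
    events = geo.flag_unnatural(series.light, events, dynamic_range=default_config.light_max)
    posts = geo.estimate_positions(events, threshold_elevation_deg=default_config.light_center_deg)
    track = geo.median_track(posts, events, default_config.colony_lat, default_config.colony_lon)
    from swiftascent.phases import great_circle_km

    m = match_truth(track, truth.twilights.rename(columns={"lat": "lat_true", "lon": "lon_true"}))
    err_km = great_circle_km(m["lat"], m["lon"], m["lat_true"], m["lon_true"])
    assert np.median(err_km) < 2 * 111.0  # two 1° grid cells


def test_equinox_latitude_spread_exceeds_longitude():
    cfg = winter_config(start="2015-03-05", end="2015-04-05",
                        breeding_end="2015-03-06", autumn_migration_end="2015-03-07",
                        nonbreeding_end="2015-04-03", spring_migration_end="2015-04-04",
                        cavity_attendance_p=0.0)
    grid = synthetic.simulate_weather_grid(cfg)
    series, _ = synthetic.simulate_annual_cycle(cfg, "e01", "pop", weather=grid)
    events = geo.detect_twilights(series.light, cfg.light_max / 2)
    events = geo.flag_unnatural(series.light, events, dynamic_range=cfg.light_max)
    posts = geo.estimate_positions(events, threshold_elevation_deg=cfg.light_center_deg)
    mid = [p for p in posts if abs((p.event_time - pd.Timestamp("2015-03-20")).days) < 5]
    lat_sd, lon_sd = [], []
    for p in mid:
        lat_m = p.mass.sum(axis=1)
        lon_m = p.mass.sum(axis=0)
        lat_sd.append(np.sqrt(np.cov(p.grid_lat, aweights=lat_m)))
        lon_sd.append(np.sqrt(np.cov(p.grid_lon, aweights=lon_m)))
    assert np.median(lat_sd) > np.median(lon_sd)


def test_all_unnatural_events_raise_position_failure():
    t = pd.date_range("2014-11-01", periods=4, freq="12h")
    events = [geo.TwilightEvent(ts, k, natural=False) for ts, k in zip(t, ["dawn", "dusk"] * 2)]
    with pytest.raises(geo.PositionFailureError):
        geo.estimate_positions(events)


# ---- sampling & interpolation ----

def _point_posterior(lat, lon, t, spread=None):
    grid = geo.GridSpec(0, 9, 0, 9, 1.0)
    mass = np.zeros((10, 10))
    if spread is None:
        mass[int(lat), int(lon)] = 1.0
    else:
        for (la, lo), w in spread.items():
            mass[la, lo] = w
    return geo.PositionPosterior(geo.TwilightEvent(pd.Timestamp(t), "dawn"), grid.lats, grid.lons, mass)


def test_degenerate_posterior_gives_identical_tracks():
    posts = [_point_posterior(3, 4, "2014-11-01 06:00"), _point_posterior(5, 6, "2014-11-01 18:00")]
    tracks = geo.sample_tracks(posts, 50, seed=1)
    assert all((t.lat == tracks[0].lat).all() and (t.lon == tracks[0].lon).all() for t in tracks)


def test_two_cell_posterior_sampling_frequencies():
    posts = [_point_posterior(0, 0, "2014-11-01 06:00", spread={(2, 2): 0.6, (7, 7): 0.4})]
    tracks = geo.sample_tracks(posts, 10_000, seed=2)
    frac = np.mean([t.lat[0] == 2 for t in tracks])
    assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 10_000) + 1e-12


def test_same_seed_identical_track_set():
    posts = [_point_posterior(0, 0, "2014-11-01 06:00", spread={(2, 2): 0.5, (7, 7): 0.5})]
    a = geo.sample_tracks(posts, 100, seed=3)
    b = geo.sample_tracks(posts, 100, seed=3)
    assert all((x.lat == y.lat).all() for x, y in zip(a, b))
    with pytest.raises(ValueError):
        geo.sample_tracks(posts, 0, seed=3)


def test_interpolate_position_rules():
    track = pd.DataFrame({
        "event_time": pd.to_datetime(["2014-11-01 06:00", "2014-11-02 06:00"]),
        "lat": [0.0, 2.0], "lon": [0.0, 2.0],
    })
    assert geo.interpolate_position(track, "2014-11-01 18:00") == (1.0, 1.0)
    assert geo.interpolate_position(track, "2014-11-02 06:00") == (2.0, 2.0)
    assert geo.interpolate_position(track, "2014-10-20", colony=(47.0, 8.0)) == (47.0, 8.0)
    with pytest.raises(ValueError):
        geo.interpolate_position(track, "2014-10-20")
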