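"""Synthetic annual cycle of multi-sensor tag data with ground truth.

One simulated deployment covers a full year in three regimes mirroring a
trans-Saharan migrant's annual cycle:

* breeding — the bird roosts in the colony cavity at night (shading the
  light sensor through twilight, producing abrupt "unnatural" light steps
  at cavity entry/exit) and flies near the colony by day;
* migration — the bird travels between the colony and a sub-Saharan
  non-breeding site in about two weeks, with sustained flapping bouts at
  2000–3000 m cruising altitude;
* non-breeding residence — the bird is airborne around the clock at a
  confined tropical site, with frequent twilight ascents.

At each twilight an ascent is drawn (Bernoulli, phase- and twilight-type-
specific probability; dusk odds are a configurable fraction of dawn odds)
and, if performed, the true altitude gets a rectangular bump covering
±30 min around the event — wide enough that the two pressure samples
nearest the twilight sit on the plateau, narrow enough that the 12-h
baseline window is untouched.  Light follows a sigmoid of solar elevation
at the true position, pressure encodes true altitude through the inverse
barometric formula against the local synthetic sea-level pressure, and
activity reflects the true behaviour (flapping / gliding / resting).

The co-registered weather field is a 2.5°, 6-hourly grid whose variability
comes from travelling synthetic pressure "fronts" (eastward-moving lows
with correlated humidity, temperature and wind anomalies).

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from . import altimetry
from .sensor_core import SensorSeries
from .solar import solar_elevation, sun_event_closed_form

PHASE_NAMES = ("breeding", "migration", "non-breeding")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class WeatherConfig:
    lat_min: float = -5.0
    lat_max: float = 60.0
    lon_min: float = -25.0
    lon_max: float = 42.5
    resolution_deg: float = 2.5
    step_hours: int = 6
    base_mslp_hpa: float = 1013.0
    front_amplitude_hpa: float = 12.0
    front_interval_days: float = 5.0
    front_speed_deg_per_day: float = 12.0
    front_width_deg: float = 8.0
    front_lat_band: tuple[float, float] = (28.0, 55.0)


@dataclass(frozen=True)
class Front:
    """A travelling low-pressure anomaly: born at ``t0`` west of the domain,
    moving east along a fixed latitude."""

    t0: pd.Timestamp
    center_lat: float
    start_lon: float
    speed_deg_per_day: float
    width_deg: float
    amplitude_hpa: float

    def center_lon(self, times) -> np.ndarray:
        days = (pd.DatetimeIndex(times) - self.t0) / pd.Timedelta(days=1)
        return self.start_lon + self.speed_deg_per_day * days.to_numpy()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated year.

    Phase boundaries and sites give a Swiss colony wintering in the West
    African highlands; default ascent probabilities put the non-breeding
    rate at twice the migration rate and twenty times the breeding rate,
    with dusk odds half of dawn odds, and a median drawn ascent height of
    about 266 m (roughly half of all ascents topping the 300-m mark).
    """

    start: str = "2014-07-20"
    end: str = "2015-07-14"
    breeding_end: str = "2014-10-06"
    autumn_migration_end: str = "2014-10-20"
    nonbreeding_end: str = "2015-04-08"
    spring_migration_end: str = "2015-04-22"

    colony_lat: float = 47.47
    colony_lon: float = 8.31
    colony_elevation_m: float = 385.0
    nonbreeding_lat: float = 9.5
    nonbreeding_lon: float = -10.0

    dawn_ascent_p: dict = field(
        default_factory=lambda: {"breeding": 0.05, "migration": 0.25, "non-breeding": 0.5}
    )
    dusk_odds_factor: float = 0.5
    ascent_height_mean_m: float = 266.0
    ascent_height_sd_m: float = 150.0
    ascent_height_min_m: float = 30.0

    breeding_day_altitude_m: float = 900.0
    migration_cruise_m: float = 1800.0
    migration_cruise_sd_m: float = 450.0
    nonbreeding_altitude_m: float = 900.0
    altitude_wobble_sd_m: float = 150.0
    altitude_wobble_tau_h: float = 36.0

    light_max: float = 64.0
    light_noise_sd: float = 1.0
    light_center_deg: float = -3.5
    light_width_deg: float = 1.5
    cavity_attendance_p: float = 0.9

    pressure_noise_sd_hpa: float = 1.0
    temperature_noise_sd_c: float = 0.5

    flap_activity_mean: float = 40.0
    flap_activity_sd: float = 6.0
    glide_activity_mean: float = 3.0
    glide_activity_sd: float = 1.2
    rest_activity_scale: float = 0.4

    weather: WeatherConfig = field(default_factory=WeatherConfig)
    seed: int = 0

    def __post_init__(self):
        for phase, p in self.dawn_ascent_p.items():
            if phase not in PHASE_NAMES:
                raise ConfigError(f"unknown phase {phase!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"ascent probability for {phase} outside [0, 1]")
        if not 0.0 <= self.cavity_attendance_p <= 1.0:
            raise ConfigError("cavity attendance probability outside [0, 1]")
        bounds = [pd.Timestamp(x) for x in (
            self.start, self.breeding_end, self.autumn_migration_end,
            self.nonbreeding_end, self.spring_migration_end, self.end)]
        if any(later <= earlier for later, earlier in zip(bounds[1:], bounds[:-1])):
            raise ConfigError("phase calendar must be strictly increasing and inside the span")

    def dusk_ascent_p(self, phase: str) -> float:
        p = self.dawn_ascent_p[phase]
        if p in (0.0, 1.0):
            return p
        odds = self.dusk_odds_factor * p / (1.0 - p)
        return odds / (1.0 + odds)

    def phase_of_date(self, when) -> str:
        t = pd.Timestamp(when)
        if t < pd.Timestamp(self.breeding_end):
            return "breeding"
        if t < pd.Timestamp(self.autumn_migration_end):
            return "migration"
        if t < pd.Timestamp(self.nonbreeding_end):
            return "non-breeding"
        if t < pd.Timestamp(self.spring_migration_end):
            return "migration"
        return "breeding"


@dataclass
class TruthRecord:
    """Ground truth for one simulated deployment."""

    twilights: pd.DataFrame  # event_time, kind, phase, lat, lon, ascent, ascent_height_m
    behaviour: pd.Series  # 5-min truth labels
    altitude: pd.Series  # 5-min true altitude (m ASL)
    position: pd.DataFrame  # 5-min true lat/lon


# --------------------------------------------------------------------------
# weather grid
# --------------------------------------------------------------------------

def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def simulate_weather_grid(config: SimulationConfig, fronts: list[Front] | None = None) -> xr.Dataset:
    """Synthetic 2.5°, 6-hourly weather field for the simulated span
    (padded ±2 days so that every twilight has its ±24-h windows).

    MSLP is the base pressure plus the travelling front anomalies only, so a
    zero front amplitude yields an exactly constant pressure field.
    Temperature carries latitude, season and a weak diurnal cycle; humidity
    and wind rise inside fronts.
    """
    wc = config.weather
    lats = _grid_axis(wc.lat_min, wc.lat_max, wc.resolution_deg)
    lons = _grid_axis(wc.lon_min, wc.lon_max, wc.resolution_deg)
    t0 = pd.Timestamp(config.start).floor("6h") - pd.Timedelta(days=2)
    t1 = pd.Timestamp(config.end) + pd.Timedelta(days=3)
    times = pd.date_range(t0, t1, freq=f"{wc.step_hours}h")

    if fronts is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 77]))
        span_days = (times[-1] - times[0]) / pd.Timedelta(days=1)
        n_fronts = int(span_days / wc.front_interval_days)
        fronts = []
        for _ in range(n_fronts):
            birth = times[0] + pd.Timedelta(days=float(rng.uniform(-5, span_days)))
            fronts.append(
                Front(
                    t0=birth,
                    center_lat=float(rng.uniform(*wc.front_lat_band)),
                    start_lon=wc.lon_min - 2.0 * wc.front_width_deg,
                    speed_deg_per_day=wc.front_speed_deg_per_day,
                    width_deg=wc.front_width_deg,
                    amplitude_hpa=wc.front_amplitude_hpa * float(rng.uniform(0.7, 1.3)),
                )
            )

    nt, ny, nx = len(times), len(lats), len(lons)
    front_field = np.zeros((nt, ny, nx))
    lat2 = lats[:, None]
    lon2 = lons[None, :]
    for fr in fronts:
        if fr.amplitude_hpa == 0:
            continue
        lon_c = fr.center_lon(times)
        active = (lon_c > wc.lon_min - 3 * fr.width_deg) & (lon_c < wc.lon_max + 3 * fr.width_deg)
        idx = np.flatnonzero(active)
        if idx.size == 0:
            continue
        dy2 = ((lat2 - fr.center_lat) / (0.75 * fr.width_deg)) ** 2
        for i in idx:
            dx2 = ((lon2 - lon_c[i]) / fr.width_deg) ** 2
            front_field[i] += fr.amplitude_hpa * np.exp(-0.5 * (dx2 + dy2))

    mslp = wc.base_mslp_hpa - front_field

    # independent smooth variability per variable (random travelling waves),
    # so the covariates are correlated with the fronts but not collinear
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 78]))
    t_days = ((times - times[0]) / pd.Timedelta(days=1)).to_numpy()[:, None, None]

    def waves(amp, n_modes=5):
        f = np.zeros((nt, ny, nx))
        for _ in range(n_modes):
            om = noise_rng.uniform(0.2, 1.2)  # cycles per day-ish scales
            ka = noise_rng.uniform(-0.15, 0.15)
            kb = noise_rng.uniform(-0.15, 0.15)
            ph = noise_rng.uniform(0, 2 * np.pi)
            f += np.sin(2 * np.pi * om * t_days + ka * lat2[None] + kb * lon2[None] + ph)
        return amp * f / np.sqrt(n_modes)

    doy = times.dayofyear.to_numpy()[:, None, None]
    hour = times.hour.to_numpy()[:, None, None]
    season = -np.cos(2 * np.pi * (doy - 15) / 365.25)
    t2m = (
        302.0
        - 0.35 * np.abs(lat2)[None]
        + 10.0 * season * (lat2[None] / 60.0)
        + 1.5 * np.cos(2 * np.pi * (hour - 14) / 24.0)
        - 0.25 * front_field
        + waves(1.5)
    )
    rh = np.clip(55.0 + 2.5 * front_field + waves(8.0), 5.0, 100.0)
    wind = np.clip(4.0 + 0.5 * front_field + waves(1.5), 0.0, None)

    ds = xr.Dataset(
        {
            "mslp": (("time", "lat", "lon"), mslp),
            "t2m": (("time", "lat", "lon"), t2m),
            "rh": (("time", "lat", "lon"), rh),
            "wind": (("time", "lat", "lon"), wind),
        },
        coords={"time": times, "lat": lats, "lon": lons},
    )
    ds.attrs["n_fronts"] = len(fronts)
    return ds


def grid_lookup(grid: xr.Dataset, var: str, lat, lon, when) -> np.ndarray:
    """Nearest-cell value in the 6-h window containing each timestamp."""
    glat = grid["lat"].to_numpy()
    glon = grid["lon"].to_numpy()
    gtime = pd.DatetimeIndex(grid["time"].to_numpy())
    step = gtime[1] - gtime[0]
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    when = pd.DatetimeIndex(np.atleast_1d(np.asarray(pd.to_datetime(when))))
    ilat = np.abs(glat[:, None] - lat[None, :]).argmin(axis=0)
    ilon = np.abs(glon[:, None] - lon[None, :]).argmin(axis=0)
    itime = np.clip(((when - gtime[0]) / step).astype(int), 0, len(gtime) - 1)
    vals = grid[var].transpose("time", "lat", "lon").to_numpy()[itime, ilat, ilon]
    return vals


# --------------------------------------------------------------------------
# annual cycle
# --------------------------------------------------------------------------

def _daily_positions(config: SimulationConfig, dates: pd.DatetimeIndex, rng) -> pd.DataFrame:
    """True position per calendar day: colony during breeding, linear legs
    with daily jitter during migration, a slow anchored random walk at the
    non-breeding site."""
    b_end = pd.Timestamp(config.breeding_end)
    am_end = pd.Timestamp(config.autumn_migration_end)
    nb_end = pd.Timestamp(config.nonbreeding_end)
    sm_end = pd.Timestamp(config.spring_migration_end)

    lat = np.full(len(dates), config.colony_lat)
    lon = np.full(len(dates), config.colony_lon)
    dlat = config.nonbreeding_lat - config.colony_lat
    dlon = config.nonbreeding_lon - config.colony_lon

    autumn = (dates >= b_end) & (dates < am_end)
    frac = ((dates[autumn] - b_end) / (am_end - b_end)).to_numpy()
    lat[autumn] = config.colony_lat + frac * dlat
    lon[autumn] = config.colony_lon + frac * dlon

    nonbr = (dates >= am_end) & (dates < nb_end)
    n_nb = int(nonbr.sum())
    walk_lat = np.zeros(n_nb)
    walk_lon = np.zeros(n_nb)
    for i in range(1, n_nb):
        walk_lat[i] = 0.9 * walk_lat[i - 1] + rng.normal(0, 0.2)
        walk_lon[i] = 0.9 * walk_lon[i - 1] + rng.normal(0, 0.15)
    lat[nonbr] = config.nonbreeding_lat + walk_lat
    lon[nonbr] = config.nonbreeding_lon + walk_lon

    spring = (dates >= nb_end) & (dates < sm_end)
    frac = ((dates[spring] - nb_end) / (sm_end - nb_end)).to_numpy()
    lat[spring] = config.nonbreeding_lat - frac * dlat
    lon[spring] = config.nonbreeding_lon - frac * dlon

    migr = autumn | spring
    lat[migr] += rng.normal(0, 0.3, int(migr.sum()))
    lon[migr] += rng.normal(0, 0.3, int(migr.sum()))
    return pd.DataFrame({"date": dates, "lat": lat, "lon": lon})


def _ou_series(n: int, dt_h: float, tau_h: float, sd: float, rng) -> np.ndarray:
    a = np.exp(-dt_h / tau_h)
    noise = rng.normal(0.0, sd * np.sqrt(1 - a * a), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return x


def simulate_annual_cycle(
    config: SimulationConfig,
    individual_id: str = "bird01",
    population_id: str = "pop1",
    weather: xr.Dataset | None = None,
) -> tuple[SensorSeries, TruthRecord]:
    """Simulate one tag deployment; deterministic given config seed and ids."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), zlib.crc32(individual_id.encode())])
    )
    if weather is None:
        weather = simulate_weather_grid(config)

    t5 = pd.date_range(config.start, config.end, freq="5min")
    dates = pd.date_range(pd.Timestamp(config.start).normalize(), pd.Timestamp(config.end).normalize(), freq="D")
    daily = _daily_positions(config, dates, rng)

    day_f = (t5 - dates[0]) / pd.Timedelta(days=1)
    day_idx = np.arange(len(dates), dtype=float)
    lat5 = np.interp(day_f, day_idx, daily["lat"].to_numpy())
    lon5 = np.interp(day_f, day_idx, daily["lon"].to_numpy())

    # ---- true twilight events (sun crossing the light-curve midpoint) ----
    tw_rows = []
    for i, d in enumerate(dates):
        la, lo = daily["lat"].iloc[i], daily["lon"].iloc[i]
        phase = config.phase_of_date(d + pd.Timedelta(hours=12))
        for kind in ("dawn", "dusk"):
            minutes = sun_event_closed_form(la, lo, d, kind, elevation=config.light_center_deg)
            if not np.isfinite(minutes):
                continue
            t_ev = d + pd.Timedelta(minutes=float(minutes))
            if not (t5[0] <= t_ev <= t5[-1]):
                continue
            p = config.dawn_ascent_p[phase] if kind == "dawn" else config.dusk_ascent_p(phase)
            ascent = bool(rng.random() < p)
            height = 0.0
            if ascent:
                height = float(
                    np.clip(
                        rng.normal(config.ascent_height_mean_m, config.ascent_height_sd_m),
                        config.ascent_height_min_m,
                        None,
                    )
                )
            tw_rows.append(
                {"event_time": t_ev, "kind": kind, "phase": phase, "lat": la, "lon": lo,
                 "ascent": ascent, "ascent_height_m": height}
            )
    twilights = pd.DataFrame(tw_rows).sort_values("event_time").reset_index(drop=True)

    # ---- true altitude and behaviour on the 5-min grid ----
    n5 = len(t5)
    phase5 = np.array([config.phase_of_date(t) for t in dates])  # per day
    phase5 = phase5[np.clip(day_f.astype(int), 0, len(dates) - 1)]
    wobble = _ou_series(n5, 5.0 / 60.0, config.altitude_wobble_tau_h, config.altitude_wobble_sd_m, rng)

    alt = np.empty(n5)
    behaviour = np.full(n5, "gliding", dtype=object)
    on_ground = np.zeros(n5, dtype=bool)

    is_breeding = phase5 == "breeding"
    is_migration = phase5 == "migration"
    is_nonbreeding = phase5 == "non-breeding"

    alt[is_nonbreeding] = config.nonbreeding_altitude_m + wobble[is_nonbreeding]
    alt[is_breeding] = config.breeding_day_altitude_m + wobble[is_breeding]
    # migration: a per-day cruising level (drawn once per travel day, applied
    # from local midday to next midday so twilight baseline windows stay on
    # one level), plus the shared slow wobble
    if is_migration.any():
        mig_level = np.empty(len(dates))
        for i in range(len(dates)):
            mig_level[i] = rng.normal(config.migration_cruise_m, config.migration_cruise_sd_m)
        noon_idx = np.clip(((t5 - (dates[0] + pd.Timedelta(hours=12))) / pd.Timedelta(days=1)).astype(int) + 1, 0, len(dates) - 1)
        alt[is_migration] = np.clip(mig_level[noon_idx], 600.0, None)[is_migration] + wobble[is_migration]

    # night-time at the colony: on the ground (roost/cavity)
    sun_night = np.zeros(n5, dtype=bool)
    dawn_by_date = {r.event_time.normalize(): r.event_time for r in twilights.itertuples() if r.kind == "dawn"}
    dusk_by_date = {r.event_time.normalize(): r.event_time for r in twilights.itertuples() if r.kind == "dusk"}
    for i, d in enumerate(dates):
        if config.phase_of_date(d + pd.Timedelta(hours=12)) != "breeding":
            continue
        dawn = dawn_by_date.get(d)
        dusk = dusk_by_date.get(d)
        if dawn is not None:
            sun_night |= (t5 >= d) & (t5 < dawn)
        if dusk is not None:
            sun_night |= (t5 >= dusk) & (t5 < d + pd.Timedelta(days=1))
    on_ground = is_breeding & sun_night
    alt[on_ground] = config.colony_elevation_m
    behaviour[on_ground] = "resting"

    # migration flapping bouts (sustained directed flight): activity regime
    # only; the cruising level itself is the per-day altitude above
    in_bout = np.zeros(n5, dtype=bool)
    for d in dates[[config.phase_of_date(d + pd.Timedelta(hours=12)) == "migration" for d in dates]]:
        dawn = dawn_by_date.get(d)
        if dawn is None:
            continue
        in_bout |= (t5 >= dawn + pd.Timedelta(hours=1)) & (t5 <= dawn + pd.Timedelta(hours=9))
    behaviour[in_bout] = "flapping"

    # twilight ascent bumps: rectangular plateau covering ±30 min
    half = pd.Timedelta(minutes=30)
    for r in twilights.itertuples():
        if not r.ascent:
            continue
        sel = (t5 >= r.event_time - half) & (t5 <= r.event_time + half)
        alt[sel] += r.ascent_height_m
        behaviour[sel & ~on_ground] = "flapping"
        behaviour[sel & on_ground] = "flapping"
        on_ground[sel] = False
    alt = np.clip(alt, 0.0, None)

    # ---- sensor channels ----
    elev5 = solar_elevation(lat5, lon5, t5)
    light = config.light_max / (1.0 + np.exp(-(elev5 - config.light_center_deg) / config.light_width_deg))

    # cavity attendance during breeding twilights: light shaded to zero
    for i, d in enumerate(dates):
        if config.phase_of_date(d + pd.Timedelta(hours=12)) != "breeding":
            continue
        dusk = dusk_by_date.get(d)
        if dusk is None or rng.random() >= config.cavity_attendance_p:
            continue
        next_dawn = dawn_by_date.get(d + pd.Timedelta(days=1))
        exit_t = (next_dawn + pd.Timedelta(minutes=30)) if next_dawn is not None else d + pd.Timedelta(hours=30)
        sel = (t5 >= dusk - pd.Timedelta(minutes=45)) & (t5 < exit_t)
        light[sel] = 0.0
    if config.light_noise_sd > 0:
        light = light + rng.normal(0, config.light_noise_sd, n5)
    light = np.clip(light, 0.0, config.light_max)

    activity = np.empty(n5)
    for label, sel in (
        ("flapping", behaviour == "flapping"),
        ("gliding", behaviour == "gliding"),
        ("resting", behaviour == "resting"),
    ):
        k = int(sel.sum())
        if label == "flapping":
            activity[sel] = np.clip(rng.normal(config.flap_activity_mean, config.flap_activity_sd, k), 0, None)
        elif label == "gliding":
            activity[sel] = np.clip(rng.normal(config.glide_activity_mean, config.glide_activity_sd, k), 0, None)
        else:
            activity[sel] = np.abs(rng.normal(0, config.rest_activity_scale, k))

    t30 = t5[::6]
    alt30 = alt[::6]
    p0_true = grid_lookup(weather, "mslp", lat5[::6], lon5[::6], t30)
    pressure = altimetry.altitude_to_pressure(alt30, p0_true)
    if config.pressure_noise_sd_hpa > 0:
        pressure = pressure + rng.normal(0, config.pressure_noise_sd_hpa, len(t30))
    t2m_true = grid_lookup(weather, "t2m", lat5[::6], lon5[::6], t30)
    temperature = t2m_true - 273.15 - 0.0065 * alt30 + rng.normal(0, config.temperature_noise_sd_c, len(t30))

    series = SensorSeries(
        individual_id=individual_id,
        population_id=population_id,
        light=pd.Series(light, index=t5),
        activity=pd.Series(activity, index=t5),
        pressure=pd.Series(pressure, index=t30),
        temperature=pd.Series(temperature, index=t30),
    )
    truth = TruthRecord(
        twilights=twilights,
        behaviour=pd.Series(behaviour, index=t5),
        altitude=pd.Series(alt, index=t5),
        position=pd.DataFrame({"lat": lat5, "lon": lon5}, index=t5),
    )
    return series, truth


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """A copy of ``config`` with all sensor noise, altitude variability and
    weather fronts switched off (used for exactness checks)."""
    return replace(
        config,
        light_noise_sd=0.0,
        pressure_noise_sd_hpa=0.0,
        temperature_noise_sd_c=0.0,
        altitude_wobble_sd_m=0.0,
        migration_cruise_sd_m=0.0,
        weather=replace(config.weather, front_amplitude_hpa=0.0),
    )
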