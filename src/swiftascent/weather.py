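"""Weather annotation of twilight events and the regression change factors.

Each twilight is matched to the 6-h forecast window containing it (an event
exactly on a window boundary belongs to the window starting there) and to
the nearest grid cell of a 2.5° reanalysis-style field at the bird's
interpolated position.  Covariates are mean sea-level pressure, 2-m
temperature, relative humidity and wind speed at 1000 mbar.

"Change" factors are the absolute differences between the event's 6-h window
and the same window 24 h before / 24 h after, for MSLP, temperature and
humidity (the sign of the change is disregarded; wind changes are excluded
by design).  All model covariates are z-transformed (mean 0, sd 1, n-1
denominator) across the dataset before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

DELTA_VARS = ("mslp", "t2m", "rh")  # wind deliberately excluded
LEVEL_VARS = ("mslp", "t2m", "rh", "wind")


class DegenerateFactorError(ValueError):
    """A covariate with zero variance cannot be z-transformed."""


class OutOfDomainError(ValueError):
    """Position or time falls outside the weather grid."""


def z_transform(values):
    """(x - mean) / sd with the n-1 sd.  Requires >= 2 distinct values."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or np.all(finite == finite[0]):
        raise DegenerateFactorError("need >= 2 distinct values to standardise")
    sd = finite.std(ddof=1)
    return (arr - finite.mean()) / sd


@dataclass(frozen=True)
class WeatherAnnotation:
    event_time: pd.Timestamp
    lat: float
    lon: float
    mslp: float
    t2m: float
    rh: float
    wind: float
    d24_before_mslp: float
    d24_after_mslp: float
    d24_before_t2m: float
    d24_after_t2m: float
    d24_before_rh: float
    d24_after_rh: float


def _window_start(times: pd.DatetimeIndex, step_h: int = 6) -> pd.DatetimeIndex:
    return times.floor(f"{step_h}h")


def annotate_weather(track: pd.DataFrame, grid: xr.Dataset, *, step_h: int = 6) -> pd.DataFrame:
    """Annotate a per-twilight track with weather and ±24-h change factors.

    ``track`` needs columns ``event_time``, ``lat``, ``lon``.  Returns one
    row per event; raw (signed-magnitude) values only — z-transformed
    columns are added by the modelling layer so that standardisation is
    always relative to the dataset actually fitted.
    """
    times = pd.DatetimeIndex(track["event_time"])
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)

    glat = grid["lat"].to_numpy()
    glon = grid["lon"].to_numpy()
    gtime = pd.DatetimeIndex(grid["time"].to_numpy())
    if lat.min() < glat.min() or lat.max() > glat.max() or lon.min() < glon.min() or lon.max() > glon.max():
        raise OutOfDomainError("track position outside the weather grid")

    win = _window_start(times, step_h)
    step = pd.Timedelta(hours=step_h)
    t0, t1 = gtime[0], gtime[-1]
    need_lo, need_hi = win.min() - pd.Timedelta(hours=24), win.max() + pd.Timedelta(hours=24)
    if need_lo < t0 or need_hi > t1:
        raise OutOfDomainError("twilight ±24 h extends beyond the weather grid time span")

    ilat = np.abs(glat[:, None] - lat[None, :]).argmin(axis=0)
    ilon = np.abs(glon[:, None] - lon[None, :]).argmin(axis=0)
    itime = ((win - t0) / step).astype(int).to_numpy()
    ishift = int(pd.Timedelta(hours=24) / step)

    out = {"event_time": times, "lat": lat, "lon": lon}
    fields = {v: grid[v].transpose("time", "lat", "lon").to_numpy() for v in LEVEL_VARS}
    for v in LEVEL_VARS:
        out[v] = fields[v][itime, ilat, ilon]
    for v in DELTA_VARS:
        cur = fields[v][itime, ilat, ilon]
        out[f"d24_before_{v}"] = np.abs(cur - fields[v][itime - ishift, ilat, ilon])
        out[f"d24_after_{v}"] = np.abs(fields[v][itime + ishift, ilat, ilon] - cur)
    return pd.DataFrame(out)
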