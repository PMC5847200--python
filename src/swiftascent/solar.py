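"""Solar geometry from standard low-precision almanac equations.

Implements the geometric (unrefracted) solar position used throughout the
pipeline: solar elevation for arbitrary timestamps and positions, and the
timestamp at which the sun crosses a configured elevation (sun events at 0°,
civil/nautical twilight bounds at -6°/-12°).  Accuracy of the underlying
ephemeris terms (declination, equation of time) is a few hundredths of a
degree over the 20th/21st century, well inside the 0.3° contract.

All timestamps are UTC (naive ``datetime64[ns]`` or anything pandas can
coerce); longitudes are decimal degrees east-positive, latitudes
north-positive (WGS-84).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "solar_elevation",
    "solar_declination_eot",
    "twilight_time",
    "NoCrossingError",
]

_J2000_UNIX = 946728000.0  # 2000-01-01T12:00:00Z in unix seconds


class NoCrossingError(ValueError):
    """The sun does not cross the requested elevation on that day (polar
    day or polar night at that latitude)."""


def _unix_seconds(timestamp) -> np.ndarray:
    ts = pd.to_datetime(timestamp)
    if isinstance(ts, pd.Timestamp):
        return np.asarray(ts.value / 1e9)
    return np.asarray(pd.DatetimeIndex(ts).asi8 / 1e9)


def solar_declination_eot(timestamp):
    """Solar declination (degrees) and equation of time (minutes).

    Low-precision series in Julian centuries from J2000; sufficient for
    twilight work (declination error < 0.01°, EoT error < 0.1 min).
    """
    t = (_unix_seconds(timestamp) - _J2000_UNIX) / (86400.0 * 36525.0)

    # geometric mean longitude / anomaly of the sun (deg)
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = np.deg2rad(357.52911 + t * (35999.05029 - 0.0001537 * t))
    ecc = 0.016708634 - t * (0.000042037 + 1.267e-7 * t)

    # equation of centre -> true longitude
    c = (
        np.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * m) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + c
    omega = np.deg2rad(125.04 - 1934.136 * t)
    lam = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    # obliquity (corrected)
    eps0 = 23.0 + (26.0 + 21.448 / 60.0) / 60.0 - t * (46.815 / 3600.0)
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))

    decl = np.rad2deg(np.arcsin(np.sin(eps) * np.sin(lam)))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.deg2rad(l0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )
    return decl, eot


def solar_elevation(lat, lon, timestamp):
    """Geometric solar elevation in degrees (no atmospheric refraction).

    Vectorised over any broadcastable combination of ``lat``, ``lon`` and
    ``timestamp``.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    lon = np.asarray(lon, dtype=float)

    secs = _unix_seconds(timestamp)
    decl, eot = solar_declination_eot(timestamp)

    minutes_utc = np.mod(secs, 86400.0) / 60.0
    # true solar time in minutes; hour angle in degrees (0 at solar noon)
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    hour_angle = np.deg2rad(tst / 4.0 - 180.0)

    phi = np.deg2rad(lat)
    dec = np.deg2rad(decl)
    sin_elev = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(hour_angle)
    return np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def _solar_noon_utc(lon, date) -> pd.Timestamp:
    day = pd.Timestamp(date).normalize()
    _, eot = solar_declination_eot(day + pd.Timedelta(hours=12))
    minutes = 720.0 - 4.0 * float(lon) - float(eot)
    return day + pd.Timedelta(minutes=minutes)


def sun_event_closed_form(lat, lon, date, kind, elevation=0.0):
    """Closed-form sun-event time from the hour-angle equation.

    Uses declination and equation of time evaluated at local solar noon.
    Vectorised over ``lat``/``lon``; cells where the sun never crosses the
    requested elevation yield NaN (minutes since midnight UTC).

    Returns minutes-since-midnight-UTC (float array or scalar); may fall
    outside [0, 1440) for longitudes where the event belongs to the
    neighbouring UTC day.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    day = pd.Timestamp(date).normalize()
    decl, eot = solar_declination_eot(day + pd.Timedelta(hours=12))

    phi = np.deg2rad(lat)
    dec = np.deg2rad(float(decl))
    cos_h = (np.sin(np.deg2rad(elevation)) - np.sin(phi) * np.sin(dec)) / (
        np.cos(phi) * np.cos(dec)
    )
    with np.errstate(invalid="ignore"):
        ha = np.rad2deg(np.arccos(np.where(np.abs(cos_h) <= 1.0, cos_h, np.nan)))
    noon = 720.0 - 4.0 * lon - float(eot)
    if kind == "dawn":
        return noon - 4.0 * ha
    if kind == "dusk":
        return noon + 4.0 * ha
    raise ValueError(f"kind must be 'dawn' or 'dusk', got {kind!r}")


def twilight_time(lat, lon, date, kind, elevation=0.0):
    """UTC timestamp at which the sun crosses ``elevation`` on ``date``.

    kind: ``"dawn"`` (upward crossing before local solar noon) or ``"dusk"``
    (downward crossing after).  The root of
    ``solar_elevation(lat, lon, t) - elevation`` is located to better than
    one second with Brent's method, seeded by the closed-form hour-angle
    solution.

    Raises :class:`NoCrossingError` during polar day / polar night.
    """
    lat = float(lat)
    lon = float(lon)
    noon = _solar_noon_utc(lon, date)
    if kind == "dawn":
        lo, hi = noon - pd.Timedelta(hours=12), noon
    elif kind == "dusk":
        lo, hi = noon, noon + pd.Timedelta(hours=12)
    else:
        raise ValueError(f"kind must be 'dawn' or 'dusk', got {kind!r}")

    def f(unix_s):
        return float(solar_elevation(lat, lon, pd.Timestamp(unix_s, unit="s"))) - elevation

    a, b = lo.value / 1e9, hi.value / 1e9
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise NoCrossingError(
            f"sun does not cross {elevation}° at lat={lat} on {pd.Timestamp(date).date()}"
        )
    root = brentq(f, a, b, xtol=1.0)
    return pd.Timestamp(root, unit="s").round("s")
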