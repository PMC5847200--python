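"""Barometric altimetry and the twilight-ascent statistic.

Flight altitude above sea level is recovered from tag pressure via the
international barometric formula

    h = (T0 / L) * (1 - (p_h / p_0) ** ((kappa - 1) / kappa))

with T0 = 288.15 K (sea-level standard temperature), L = dT/dh = 0.0065 K/m
and heat-capacity ratio kappa = 1.235.  p_h is the pressure at the bird and
p_0 the sea-level pressure at its (approximate) position; because light-level
positions are coarse, altitudes are strictly ASL, never above ground.

The twilight-ascent statistic per sun event is:

* altitude at twilight — mean of the two pressure-derived altitudes nearest
  the event in time;
* baseline altitude — mean altitude over 6 h before and 6 h after the event,
  excluding the hour containing the event itself (a 12-h reference window);
* ascent height — their difference; an "ascent" is a height of at least the
  threshold (default 300 m, inclusive; 100 m supported as a robustness
  alternative).

Also provides the sight-line geometry of an ascent: the distance to the
horizon gained, and how much earlier the sun becomes visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

DEFAULT_ASCENT_THRESHOLD_M = 300.0


@dataclass(frozen=True)
class BarometricConstants:
    """Standard-atmosphere constants for the pressure-altitude conversion."""

    t0_kelvin: float = 288.15
    lapse_k_per_m: float = 0.0065
    kappa: float = 1.235

    def __post_init__(self):
        if min(self.t0_kelvin, self.lapse_k_per_m, self.kappa) <= 0:
            raise ValueError("barometric constants must be positive")

    @property
    def exponent(self) -> float:
        return (self.kappa - 1.0) / self.kappa


STANDARD_ATMOSPHERE = BarometricConstants()


class MissingDataError(ValueError):
    """Not enough pressure samples around a twilight to form the statistic."""


def pressure_to_altitude(p_h, p_0, constants: BarometricConstants = STANDARD_ATMOSPHERE):
    """Altitude (m ASL) from tag pressure ``p_h`` and sea-level pressure
    ``p_0`` (both hPa).  Vectorised; monotone decreasing in ``p_h``."""
    p_h = np.asarray(p_h, dtype=float)
    p_0 = np.asarray(p_0, dtype=float)
    if np.any(p_h <= 0) or np.any(p_0 <= 0):
        raise ValueError("pressures must be positive")
    h = (constants.t0_kelvin / constants.lapse_k_per_m) * (
        1.0 - (p_h / p_0) ** constants.exponent
    )
    return h if h.ndim else float(h)


def altitude_to_pressure(h, p_0, constants: BarometricConstants = STANDARD_ATMOSPHERE):
    """Analytic inverse of :func:`pressure_to_altitude` (used by the
    synthetic generator to encode a true altitude as tag pressure)."""
    h = np.asarray(h, dtype=float)
    p_0 = np.asarray(p_0, dtype=float)
    base = 1.0 - h * constants.lapse_k_per_m / constants.t0_kelvin
    if np.any(base <= 0):
        raise ValueError("altitude above the top of the model atmosphere")
    p = p_0 * base ** (1.0 / constants.exponent)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class AscentRecord:
    """The per-twilight ascent statistic."""

    event_time: pd.Timestamp
    event_type: str  # "dawn" | "dusk"
    altitude_at_twilight_m: float
    baseline_altitude_m: float
    ascent_height_m: float
    is_ascent: bool
    threshold_m: float
    n_twilight_samples: int
    n_baseline_samples: int


def altitude_at_twilight(altitudes: pd.Series, event_time, *, window=pd.Timedelta(minutes=90)):
    """Mean of the two altitude samples nearest the event (m ASL).

    Requires at least two non-NaN samples within ±``window``; ties on
    distance are broken toward the earlier sample.
    """
    event_time = pd.Timestamp(event_time)
    alt = altitudes.dropna()
    near = alt[(alt.index >= event_time - window) & (alt.index <= event_time + window)]
    if len(near) < 2:
        raise MissingDataError(f"fewer than 2 altitude samples within ±{window} of {event_time}")
    dist = np.abs((near.index - event_time).to_numpy())
    order = np.argsort(dist, kind="stable")  # stable: earlier sample wins ties
    picked = near.iloc[order[:2]]
    return float(picked.mean()), 2


def baseline_altitude(
    altitudes: pd.Series,
    event_time,
    *,
    half_window=pd.Timedelta(hours=6),
    exclusion=pd.Timedelta(minutes=30),
    min_coverage: float = 0.5,
    sample_step=pd.Timedelta(minutes=30),
):
    """Mean altitude over ``half_window`` each side of the event, excluding
    ±``exclusion`` around the event (the twilight hour itself).

    Fails with :class:`MissingDataError` when fewer than ``min_coverage`` of
    the expected 30-min samples in the window are present.
    """
    event_time = pd.Timestamp(event_time)
    alt = altitudes.dropna()
    lo = event_time - half_window - exclusion
    hi = event_time + half_window + exclusion
    idx = alt.index
    in_window = (idx >= lo) & (idx <= hi)
    near_event = (idx >= event_time - exclusion) & (idx <= event_time + exclusion)
    sel = alt[in_window & ~near_event]
    expected = int(2 * half_window / sample_step)
    if len(sel) < min_coverage * expected:
        raise MissingDataError(
            f"baseline coverage {len(sel)}/{expected} below {min_coverage:.0%} at {event_time}"
        )
    return float(sel.mean()), int(len(sel))


def ascent_height(
    altitudes: pd.Series,
    event_time,
    event_type: str,
    *,
    threshold_m: float = DEFAULT_ASCENT_THRESHOLD_M,
    half_window=pd.Timedelta(hours=6),
) -> AscentRecord:
    """Build the :class:`AscentRecord` for one twilight event.

    ``ascent_height = altitude_at_twilight - baseline_altitude``; the ascent
    flag is inclusive at the threshold.  Missing-data conditions from either
    sub-statistic propagate.
    """
    at_twi, n_twi = altitude_at_twilight(altitudes, event_time)
    base, n_base = baseline_altitude(altitudes, event_time, half_window=half_window)
    height = at_twi - base
    return AscentRecord(
        event_time=pd.Timestamp(event_time),
        event_type=event_type,
        altitude_at_twilight_m=at_twi,
        baseline_altitude_m=base,
        ascent_height_m=height,
        is_ascent=bool(height >= threshold_m),
        threshold_m=threshold_m,
        n_twilight_samples=n_twi,
        n_baseline_samples=n_base,
    )


def horizon_distance(h_m) -> float:
    """Distance to the horizon (km) gained by an ascent to ``h_m`` metres:
    sqrt(2 R h).  A 300-m ascent reveals roughly 60 km beyond the horizon."""
    h_m = np.asarray(h_m, dtype=float)
    if np.any(h_m < 0):
        raise ValueError("height must be >= 0")
    d = np.sqrt(2.0 * EARTH_RADIUS_KM * (h_m / 1000.0))
    return d if d.ndim else float(d)


def sunrise_advance(h_m, solar_rate_deg_per_min: float = 0.25) -> float:
    """Minutes earlier the sun rises for a bird at ``h_m`` metres: the
    horizon dip arccos(R/(R+h)) divided by the mean solar angular rate."""
    h_m = np.asarray(h_m, dtype=float)
    if np.any(h_m < 0):
        raise ValueError("height must be >= 0")
    dip_deg = np.rad2deg(np.arccos(EARTH_RADIUS_KM / (EARTH_RADIUS_KM + h_m / 1000.0)))
    adv = dip_deg / solar_rate_deg_per_min
    return adv if adv.ndim else float(adv)
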