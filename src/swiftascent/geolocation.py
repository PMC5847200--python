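"""Threshold-light geolocation with a grid hidden-Markov smoother.

The chain is: detect twilight events from the 5-min light series (threshold
method with linear interpolation between bracketing samples); flag events as
unnatural when the light jumps abruptly near the event (cavity entry/exit
shading, not the sun); then place each natural event on a lat/lon grid.

Positioning uses a per-event likelihood from the mismatch between the
observed twilight time and the time predicted for each grid cell (hour-angle
equation), combined with a Gaussian random-walk movement prior between
consecutive sun events, smoothed by forward–backward recursion.  The output
per event is a normalised probability mass over the grid, from which median
positions and bootstrap track draws derive.  Unnatural events never get a
posterior; their positions are linearly interpolated between neighbouring
natural medians, pinned to the colony outside the span of natural events
(birds are assumed at the colony before the first and after the last natural
sun event of the deployment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .solar import sun_event_closed_form

__all__ = [
    "TwilightEvent",
    "PositionPosterior",
    "TrackEstimate",
    "GridSpec",
    "detect_twilights",
    "flag_unnatural",
    "forward_backward",
    "estimate_positions",
    "median_track",
    "sample_tracks",
    "interpolate_position",
    "PositionFailureError",
]


class PositionFailureError(ValueError):
    """No natural events available: positions cannot be estimated."""


EMISSION_FLOOR = 1e-6  # uniform mixture weight in the twilight likelihood


@dataclass(frozen=True)
class TwilightEvent:
    timestamp: pd.Timestamp
    kind: str  # "dawn" | "dusk"
    natural: bool = True
    source: str = "observed-threshold"  # or "computed-astronomical"

    def __post_init__(self):
        if self.kind not in ("dawn", "dusk"):
            raise ValueError(f"kind must be dawn/dusk, got {self.kind!r}")


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid; cells indexed by their centres (WGS-84
    decimal degrees, east/north positive)."""

    lat_min: float = -5.0
    lat_max: float = 60.0
    lon_min: float = -25.0
    lon_max: float = 42.0
    resolution_deg: float = 1.0

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.resolution_deg)) + 1
        return self.lat_min + self.resolution_deg * np.arange(n)

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.resolution_deg)) + 1
        return self.lon_min + self.resolution_deg * np.arange(n)


@dataclass
class PositionPosterior:
    event: TwilightEvent
    grid_lat: np.ndarray
    grid_lon: np.ndarray
    mass: np.ndarray = field(repr=False)  # (n_lat, n_lon), sums to 1

    @property
    def event_time(self) -> pd.Timestamp:
        return self.event.timestamp

    def median_position(self) -> tuple[float, float]:
        """Weighted medians of the marginal lat / lon distributions."""
        lat_marg = self.mass.sum(axis=1)
        lon_marg = self.mass.sum(axis=0)
        return (
            _weighted_median(self.grid_lat, lat_marg),
            _weighted_median(self.grid_lon, lon_marg),
        )


@dataclass
class TrackEstimate:
    event_times: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    provenance: str  # "median" | "sampled"
    sample_seed: int | None = None


def _weighted_median(values, weights):
    cum = np.cumsum(weights) / np.sum(weights)
    return float(values[int(np.searchsorted(cum, 0.5))])


# --------------------------------------------------------------------------
# twilight detection & unnatural flagging
# --------------------------------------------------------------------------

def _runs(states: np.ndarray):
    """Run-length encode a boolean array as (start, stop, state) with stop
    exclusive."""
    change = np.flatnonzero(np.diff(states.astype(np.int8)))
    bounds = np.concatenate(([0], change + 1, [len(states)]))
    return [(int(bounds[i]), int(bounds[i + 1]), bool(states[bounds[i]])) for i in range(len(bounds) - 1)]


def detect_twilights(
    light: pd.Series,
    threshold: float,
    *,
    min_day_duration=pd.Timedelta(hours=3),
    min_night_duration=pd.Timedelta(minutes=30),
):
    """Threshold twilight events from a 5-min light series.

    Daylight blocks are maximal runs with light strictly above the threshold;
    runs shorter than ``min_day_duration`` (flickers from noise near the
    threshold) and intervening dips shorter than ``min_night_duration`` are
    absorbed, so the dawn is the last upward threshold crossing of the
    morning and the dusk the first downward crossing of the evening.  Event
    timestamps are linearly interpolated between the two bracketing samples;
    a sample exactly at the threshold counts as night, so a crossing starting
    at such a sample is assigned to the interval beginning there.
    """
    light = light.dropna()
    if len(light) < 2:
        warnings.warn("light series too short for twilight detection")
        return []
    values = light.to_numpy(dtype=float)
    times = light.index
    step = times[1] - times[0]
    above = values > threshold
    if above.all() or (~above).all():
        warnings.warn("light never crosses the threshold: no twilight events")
        return []

    # absorb short dips into day, then drop short day flickers
    for min_len, state in ((min_night_duration, False), (min_day_duration, True)):
        n_min = max(int(min_len / step), 1)
        for s, e, st in _runs(above):
            if st == state and e - s < n_min and s > 0 and e < len(above):
                above[s:e] = not state

    def crossing_time(i):
        # crossing between samples i-1 and i (state change at i)
        l0, l1 = values[i - 1], values[i]
        frac = 0.0 if l1 == l0 else float(np.clip((threshold - l0) / (l1 - l0), 0.0, 1.0))
        return times[i - 1] + frac * step

    events: list[TwilightEvent] = []
    for s, e, st in _runs(above):
        if not st:
            continue
        if s > 0:
            events.append(TwilightEvent(crossing_time(s), "dawn"))
        if e < len(values):
            events.append(TwilightEvent(crossing_time(e), "dusk"))
    events.sort(key=lambda ev: ev.timestamp)
    return events


def flag_unnatural(
    light: pd.Series,
    events,
    *,
    fraction: float = 0.8,
    dynamic_range: float | None = None,
    window=pd.Timedelta(minutes=30),
):
    """Set the natural flag: an event is unnatural when any single 5-min
    light step within ±``window`` of it is at least ``fraction`` of the
    sensor's dynamic range (boundary inclusive).  Such steps are the
    signature of a bird entering or leaving the breeding cavity rather than
    of the sun."""
    light = light.dropna()
    if dynamic_range is None:
        dynamic_range = float(light.max() - light.min())
    steps = light.diff().abs()
    cut = fraction * dynamic_range
    flagged = []
    for ev in events:
        near = steps[(steps.index > ev.timestamp - window) & (steps.index <= ev.timestamp + window)]
        flagged.append(replace(ev, natural=bool(not (near >= cut).any())))
    return flagged


# --------------------------------------------------------------------------
# grid HMM
# --------------------------------------------------------------------------

def forward_backward(emissions, transition):
    """Posterior state probabilities of a hidden Markov chain.

    Parameters
    ----------
    emissions : array (T, ...) of non-negative likelihoods (any state shape).
    transition : either a (K, K) row-stochastic matrix ``T[i, j] = P(j | i)``
        over flattened states, or a callable applying a *symmetric*
        transition kernel to a state-shaped array (e.g. a Gaussian blur).

    Returns array of the same shape as ``emissions`` with each time slice
    normalised to sum to 1.  Scaled (normalised) alpha/beta recursions keep
    the computation stable for long chains.
    """
    em = [np.asarray(e, dtype=float) for e in emissions]
    T = len(em)
    shape = em[0].shape

    if callable(transition):
        fwd_op = bwd_op = transition
    else:
        mat = np.asarray(transition, dtype=float)

        def fwd_op(v):
            return (v.reshape(-1) @ mat).reshape(shape)

        def bwd_op(v):
            return (mat @ v.reshape(-1)).reshape(shape)

    alphas = []
    a = em[0] / em[0].sum()
    alphas.append(a)
    for t in range(1, T):
        a = fwd_op(a) * em[t]
        s = a.sum()
        if s == 0:
            raise PositionFailureError(f"zero forward probability at step {t}")
        a = a / s
        alphas.append(a)

    b = np.ones(shape)
    posts = [None] * T
    posts[T - 1] = alphas[-1]
    for t in range(T - 2, -1, -1):
        b = bwd_op(b * em[t + 1])
        b = b / b.max()
        g = alphas[t] * b
        posts[t] = g / g.sum()
    return np.stack(posts)


def _emission_grid(
    event: TwilightEvent, grid: GridSpec, sigma_minutes: float, threshold_elevation_deg: float
) -> np.ndarray:
    """Per-cell likelihood of the observed twilight time."""
    lat2, lon2 = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    pred = sun_event_closed_form(
        lat2, lon2, event.timestamp, event.kind, elevation=threshold_elevation_deg
    )
    obs = (event.timestamp - event.timestamp.normalize()) / pd.Timedelta(minutes=1)
    resid = np.mod(obs - pred + 720.0, 1440.0) - 720.0
    with np.errstate(invalid="ignore"):
        lik = np.exp(-0.5 * (resid / sigma_minutes) ** 2)
    lik[~np.isfinite(lik)] = 0.0  # cells with no sun event that day
    if lik.sum() == 0:
        lik[:] = 1.0  # uninformative event
    # robust floor: a small uniform component guards against outlier
    # twilights and keeps the recursion away from numerical zero
    return (1.0 - EMISSION_FLOOR) * lik / lik.max() + EMISSION_FLOOR


def estimate_positions(
    events,
    grid: GridSpec = GridSpec(),
    *,
    movement_sd_deg: float = 1.0,
    twilight_sd_minutes: float = 8.0,
    threshold_elevation_deg: float = 0.0,
):
    """Grid-HMM posterior for every natural event.

    Emission: Gaussian likelihood of the observed-vs-predicted twilight-time
    residual per cell, with twilight predicted at the sun elevation the
    light threshold corresponds to (``threshold_elevation_deg``, the
    calibration a template fit would supply).  Transition: Gaussian random
    walk (sd in degrees per sun event) applied as a separable blur.  Returns
    a list of :class:`PositionPosterior`, one per natural event, each
    summing to 1.
    """
    natural = [ev for ev in events if ev.natural]
    if len(natural) < 2:
        raise PositionFailureError("need at least 2 natural events to estimate positions")

    sigma_cells = movement_sd_deg / grid.resolution_deg

    def blur(v):
        return gaussian_filter(v, sigma=sigma_cells, mode="constant")

    emissions = [
        _emission_grid(ev, grid, twilight_sd_minutes, threshold_elevation_deg) for ev in natural
    ]
    post = forward_backward(emissions, blur)
    return [
        PositionPosterior(ev, grid.lats, grid.lons, post[i])
        for i, ev in enumerate(natural)
    ]


def median_track(posteriors, events, colony_lat: float, colony_lon: float) -> pd.DataFrame:
    """Per-twilight median positions for *all* events.

    Natural events take their posterior's marginal median; unnatural events
    are linearly interpolated in time between the neighbouring natural
    medians, and pinned to the colony before the first / after the last
    natural event.
    """
    by_time = {p.event_time: p.median_position() for p in posteriors}
    nat_times = sorted(by_time)
    if not nat_times:
        raise PositionFailureError("no posteriors available")
    rows = []
    for ev in events:
        t = ev.timestamp
        if t in by_time:
            lat, lon = by_time[t]
            prov = "median"
        elif t < nat_times[0] or t > nat_times[-1]:
            lat, lon = colony_lat, colony_lon
            prov = "colony-pinned"
        else:
            i = np.searchsorted(pd.DatetimeIndex(nat_times).asi8, t.value)
            t0, t1 = nat_times[i - 1], nat_times[i]
            w = (t - t0) / (t1 - t0)
            (la0, lo0), (la1, lo1) = by_time[t0], by_time[t1]
            lat, lon = la0 + w * (la1 - la0), lo0 + w * (lo1 - lo0)
            prov = "interpolated"
        rows.append(
            {"event_time": t, "kind": ev.kind, "natural": ev.natural,
             "lat": lat, "lon": lon, "provenance": prov}
        )
    return pd.DataFrame(rows)


def refine_event_times(track: pd.DataFrame, threshold_elevation_deg: float = 0.0) -> pd.DataFrame:
    """Replace the timestamps of unnatural events with the astronomical
    twilight time at the event's (interpolated or colony-pinned) position.

    A light-step caused by cavity entry/exit records when the bird moved,
    not when the sun crossed the threshold; the sun-event time for those
    days must come from the solar almanac at the approximate position.
    Natural events keep their observed threshold times.  Adds a ``source``
    column (observed-threshold / computed-astronomical).
    """
    out = track.copy()
    out["source"] = np.where(out["natural"], "observed-threshold", "computed-astronomical")
    for i, r in enumerate(out.itertuples()):
        if r.natural:
            continue
        day = r.event_time.normalize()
        minutes = sun_event_closed_form(r.lat, r.lon, day, r.kind, elevation=threshold_elevation_deg)
        if np.isfinite(minutes):
            out.iloc[i, out.columns.get_loc("event_time")] = day + pd.Timedelta(minutes=float(minutes))
    return out.sort_values("event_time").reset_index(drop=True)


def sample_tracks(posteriors, n: int, seed: int):
    """Draw ``n`` bootstrap tracks, one independent cell per event according
    to its posterior mass.  Deterministic given ``seed``."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    times = pd.DatetimeIndex([p.event_time for p in posteriors])
    T = len(posteriors)
    lat = np.empty((n, T))
    lon = np.empty((n, T))
    for j, p in enumerate(posteriors):
        flat = p.mass.reshape(-1)
        idx = rng.choice(flat.size, size=n, p=flat / flat.sum())
        ii, jj = np.unravel_index(idx, p.mass.shape)
        lat[:, j] = p.grid_lat[ii]
        lon[:, j] = p.grid_lon[jj]
    return [
        TrackEstimate(times, lat[k], lon[k], provenance="sampled", sample_seed=seed)
        for k in range(n)
    ]


def track_positions(track, times, *, colony: tuple[float, float] | None = None):
    """Vectorised :func:`interpolate_position` over many timestamps.

    Returns an (n, 2) array of lat/lon.  Timestamps outside the track span
    take the colony position (or raise when no colony is given).
    """
    if isinstance(track, TrackEstimate):
        ev_times, lat, lon = track.event_times, track.lat, track.lon
    else:
        ev_times = pd.DatetimeIndex(track["event_time"])
        lat = track["lat"].to_numpy(dtype=float)
        lon = track["lon"].to_numpy(dtype=float)
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(pd.to_datetime(times)))).asi8
    x = ev_times.asi8.astype(float)
    out = np.column_stack([np.interp(t, x, lat), np.interp(t, x, lon)])
    outside = (t < x[0]) | (t > x[-1])
    if outside.any():
        if colony is None:
            raise ValueError("timestamps outside track span and no colony pinning configured")
        out[outside] = colony
    return out


def interpolate_position(track, timestamp, *, colony: tuple[float, float] | None = None):
    """Linear interpolation of a per-twilight track at an arbitrary time.

    Outside the track span the position is the colony when given (the bird
    is assumed to reside there before the first and after the last natural
    event); otherwise an out-of-range error.
    """
    if isinstance(track, TrackEstimate):
        times, lat, lon = track.event_times, track.lat, track.lon
    else:
        times = pd.DatetimeIndex(track["event_time"])
        lat = track["lat"].to_numpy(dtype=float)
        lon = track["lon"].to_numpy(dtype=float)
    t = pd.Timestamp(timestamp)
    if t < times[0] or t > times[-1]:
        if colony is not None:
            return float(colony[0]), float(colony[1])
        raise ValueError(f"{t} outside track span and no colony pinning configured")
    x = times.asi8.astype(float)
    return (
        float(np.interp(t.value, x, lat)),
        float(np.interp(t.value, x, lon)),
    )
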