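"""Flight-behaviour classification from activity and pressure variance.

Each 5-min interval gets one of three labels:

* flapping — activity at or above the flap threshold (sustained wing-beat
  bursts);
* resting — activity below the rest threshold *and* low rolling pressure
  variance (on the ground the barometric trace is flat apart from sensor
  noise; a drifting, gliding bird keeps changing altitude);
* gliding — everything else (airborne, little flapping).

The pressure-variance criterion, not the pressure level, separates ground
from air, so the classification is invariant to any constant altitude
offset.  Thresholds are configuration, calibrated against the synthetic
generator's activity regimes (flap threshold near the flapping regime's
5th percentile, rest threshold near the resting regime's 95th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor_core import BehaviourLabel


@dataclass(frozen=True)
class BehaviourParams:
    flap_threshold: float = 30.0
    rest_threshold: float = 0.8
    ground_variance_hpa2: float = 3.0
    variance_window: pd.Timedelta = pd.Timedelta(hours=3)
    min_variance_samples: int = 3


class NoOverlapError(ValueError):
    pass


def rolling_pressure_variance(pressure: pd.Series, params: BehaviourParams = BehaviourParams()) -> pd.Series:
    """Rolling variance of the 30-min pressure channel (hPa²).

    For each sample the variance window may sit centred on, trailing, or
    leading the sample, and the smallest of the three is kept: a bird that
    has just landed (or is about to take off) is judged by the flat part of
    its trace rather than by a window straddling the landing flight.  Edges
    use whatever samples are available, with a minimum of
    ``min_variance_samples``.
    """
    step = pressure.index[1] - pressure.index[0] if len(pressure) > 1 else pd.Timedelta(minutes=30)
    win = max(int(params.variance_window / step) + 1, params.min_variance_samples)
    centred = pressure.rolling(win, center=True, min_periods=params.min_variance_samples).var()
    trailing = pressure.rolling(win, min_periods=params.min_variance_samples).var()
    leading = trailing.shift(-(win - 1))
    return pd.concat([centred, trailing, leading], axis=1).min(axis=1)


def classify_behaviour(
    activity: pd.Series,
    pressure: pd.Series,
    params: BehaviourParams = BehaviourParams(),
    *,
    as_series: bool = True,
):
    """Label every 5-min activity sample that overlaps the pressure record.

    Returns a pandas Series of labels on the activity grid (or a list of
    :class:`BehaviourLabel` with ``as_series=False``).  Labels partition the
    classified span: each interval gets exactly one label.
    """
    act = activity.dropna()
    pres = pressure.dropna()
    if act.empty or pres.empty:
        raise NoOverlapError("activity and pressure channels do not overlap")
    lo, hi = max(act.index[0], pres.index[0]), min(act.index[-1], pres.index[-1])
    if lo > hi:
        raise NoOverlapError("activity and pressure channels do not overlap")
    act = act[(act.index >= lo) & (act.index <= hi)]

    var30 = rolling_pressure_variance(pres, params)
    # nearest-sample alignment of the 30-min variance onto the 5-min grid
    var5 = var30.reindex(var30.index.union(act.index)).interpolate("nearest").reindex(act.index)
    var5 = var5.ffill().bfill()

    labels = np.full(len(act), "gliding", dtype=object)
    a = act.to_numpy()
    v = var5.to_numpy()
    labels[a >= params.flap_threshold] = "flapping"
    labels[(a < params.rest_threshold) & (v < params.ground_variance_hpa2)] = "resting"
    out = pd.Series(labels, index=act.index, name="behaviour")
    if as_series:
        return out
    return [BehaviourLabel(t, l) for t, l in out.items()]


def hourly_summary(labels: pd.Series) -> pd.DataFrame:
    """Hour-of-day × date frequency table per behaviour (the aggregation
    behind a population-level activity heat map)."""
    df = labels.to_frame("label")
    df["date"] = df.index.normalize()
    df["hour"] = df.index.hour
    counts = df.groupby(["date", "hour", "label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0).reset_index()
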