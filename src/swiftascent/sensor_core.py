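"""Core tag-data model: per-individual sensor channels and burst summaries.

A deployed tag records light and a vertical-acceleration activity summary
every 5 minutes and air pressure / temperature every 30 minutes.  Tags store
only the burst summaries (activity, pitch), never the raw 10 Hz bursts; the
burst-to-summary conversions live here so the synthetic generator can
optionally emit raw bursts and so their definitions are pinned down:

* activity — cumulative absolute change of z-axis acceleration over a 3.2-s
  burst sampled at 10 Hz (32 samples); a proxy for wing-flapping intensity.
* pitch — mean z-axis acceleration over the same burst (gravitational
  component; not used by the downstream analysis).

Timestamps are UTC throughout.  Gaps (tag dropouts) are represented as NaN
values on the regular sampling grid, never interpolated at this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

BURST_SAMPLES = 32  # 10 Hz over 3.2 s
SENSOR_RANGE_G = 16.0

LIGHT_STEP = pd.Timedelta(minutes=5)
PRESSURE_STEP = pd.Timedelta(minutes=30)


class MalformedBurstError(ValueError):
    """Raised when an acceleration burst has the wrong sample count or
    values outside the sensor range."""


@dataclass(frozen=True)
class AccelBurst:
    """One 3.2-s vertical-acceleration burst (32 samples at 10 Hz, in g)."""

    samples: np.ndarray
    sensor_range_g: float = SENSOR_RANGE_G

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.shape != (BURST_SAMPLES,):
            raise MalformedBurstError(
                f"burst must have exactly {BURST_SAMPLES} samples, got {arr.shape}"
            )
        if np.any(np.abs(arr) > self.sensor_range_g):
            raise MalformedBurstError("burst sample outside sensor range")
        object.__setattr__(self, "samples", arr)


def activity_from_burst(burst: AccelBurst) -> float:
    """Cumulative absolute change in z-acceleration over the burst (>= 0)."""
    return float(np.sum(np.abs(np.diff(burst.samples))))


def pitch_from_burst(burst: AccelBurst) -> float:
    """Mean z-acceleration over the burst (g)."""
    return float(np.mean(burst.samples))


BEHAVIOUR_LABELS = ("flapping", "gliding", "resting")


@dataclass(frozen=True)
class BehaviourLabel:
    timestamp: pd.Timestamp
    label: str

    def __post_init__(self):
        if self.label not in BEHAVIOUR_LABELS:
            raise ValueError(f"unknown behaviour label {self.label!r}")


def _as_channel(data, step: pd.Timedelta, name: str) -> pd.Series:
    s = pd.Series(dict(data)) if not isinstance(data, pd.Series) else data.copy()
    s.index = pd.DatetimeIndex(s.index)
    s = s.astype(float)
    s.name = name
    if len(s) > 1:
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValueError(f"{name}: timestamps must be strictly increasing")
        offsets = (s.index - s.index[0]) % step
        if not (offsets == pd.Timedelta(0)).all():
            raise ValueError(f"{name}: timestamps not on a {step} grid")
    return s


@dataclass
class SensorSeries:
    """All channels recorded by one tag deployment.

    ``light`` and ``activity`` sit on a 5-min grid, ``pressure`` and
    ``temperature`` on a 30-min grid aligned with it.  NaN marks dropouts.
    """

    individual_id: str
    population_id: str
    light: pd.Series = field(repr=False)
    activity: pd.Series = field(repr=False)
    pressure: pd.Series = field(repr=False)
    temperature: pd.Series = field(repr=False)

    def __post_init__(self):
        self.light = _as_channel(self.light, LIGHT_STEP, "light")
        self.activity = _as_channel(self.activity, LIGHT_STEP, "activity")
        self.pressure = _as_channel(self.pressure, PRESSURE_STEP, "pressure")
        self.temperature = _as_channel(self.temperature, PRESSURE_STEP, "temperature")
        act = self.activity.dropna()
        if (act < 0).any():
            raise ValueError("activity must be >= 0")
        pres = self.pressure.dropna()
        if ((pres <= 300) | (pres >= 1100)).any():
            raise ValueError("pressure outside plausible (300, 1100) hPa range")
        if len(self.pressure) and len(self.light):
            # the 30-min grid must be a coarsening of the 5-min grid
            if ((self.pressure.index - self.light.index[0]) % LIGHT_STEP != pd.Timedelta(0)).any():
                raise ValueError("pressure grid not aligned with the 5-min light grid")

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        idx = self.light.index
        return idx[0], idx[-1]

    # ---- tag CSV dialect: long format (timestamp, channel, value) ----

    def to_csv(self, path) -> None:
        frames = []
        for name in ("light", "activity", "pressure", "temperature"):
            s = getattr(self, name)
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": s.index.strftime("%Y-%m-%dT%H:%M:%S"),
                        "channel": name,
                        "value": s.to_numpy(),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, individual_id: str, population_id: str) -> "SensorSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        chans = {}
        for name, grp in df.groupby("channel"):
            chans[name] = pd.Series(grp["value"].to_numpy(), index=pd.DatetimeIndex(grp["timestamp"]))
        missing = {"light", "activity", "pressure", "temperature"} - set(chans)
        if missing:
            raise ValueError(f"tag file {path} missing channels: {sorted(missing)}")
        return cls(individual_id, population_id, chans["light"], chans["activity"],
                   chans["pressure"], chans["temperature"])


@dataclass(frozen=True)
class DeploymentInfo:
    individual_id: str
    population_id: str
    colony_lat: float
    colony_lon: float
    deployment_start: pd.Timestamp
    deployment_end: pd.Timestamp
    tag_file: str


def write_manifest(path, deployments: Iterable[DeploymentInfo]) -> None:
    doc = {
        "individuals": [
            {
                "individual_id": d.individual_id,
                "population_id": d.population_id,
                "colony_lat": float(d.colony_lat),
                "colony_lon": float(d.colony_lon),
                "deployment_start": str(pd.Timestamp(d.deployment_start)),
                "deployment_end": str(pd.Timestamp(d.deployment_end)),
                "tag_file": d.tag_file,
            }
            for d in deployments
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path) -> list[DeploymentInfo]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        DeploymentInfo(
            individual_id=str(e["individual_id"]),
            population_id=str(e["population_id"]),
            colony_lat=float(e["colony_lat"]),
            colony_lon=float(e["colony_lon"]),
            deployment_start=pd.Timestamp(e["deployment_start"]),
            deployment_end=pd.Timestamp(e["deployment_end"]),
            tag_file=str(e["tag_file"]),
        )
        for e in doc["individuals"]
    ]
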