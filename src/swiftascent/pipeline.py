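"""End-to-end pipeline: simulate (or load) → geolocate → ascents →
behaviour → weather annotation → model ensemble.

Every stage writes its artifacts under the configured output directory with
the configuration hash and master seed in the file names, logs audit
counters (events detected, events flagged unnatural, records dropped), and
any failure raises a :class:`StageError` naming the stage together with a
manifest of the artifacts written so far.  A run is deterministic given its
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import altimetry, behaviour as behaviour_mod, geolocation, inference, phases, synthetic, weather as weather_mod
from .sensor_core import DeploymentInfo, SensorSeries, read_manifest, write_manifest

log = logging.getLogger("swiftascent")

STAGES = ("simulate", "geolocate", "ascents", "behaviour", "annotate", "model")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, artifacts=()):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
        self.artifacts = list(artifacts)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Defaults follow the analysis design: 300-m ascent threshold, 0.8
    dynamic-range fraction for unnatural light steps, 1° positional grid,
    10,000 bootstrap tracks and 100 model-ensemble runs.
    """

    output_dir: str = "runs/demo"
    populations: tuple = (("pop1", 3), ("pop2", 3))
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    tag_manifest: str | None = None  # real-data mode: load tags instead of simulating
    weather_file: str | None = None

    light_threshold: float | None = None  # default: half the light dynamic range
    threshold_elevation_deg: float | None = None  # default: the simulated light curve's midpoint
    unnatural_fraction: float = 0.8
    ascent_threshold_m: float = 300.0
    grid: geolocation.GridSpec = field(default_factory=geolocation.GridSpec)
    movement_sd_deg: float = 1.0
    twilight_sd_minutes: float = 8.0
    n_bootstrap_tracks: int = 10_000
    n_model_runs: int = 100
    seed: int = 1

    def threshold(self) -> float:
        return self.light_threshold if self.light_threshold is not None else self.sim.light_max / 2.0

    def config_hash(self) -> str:
        # hash the scientific configuration only, not where it is written
        return hashlib.sha1(repr(dataclasses.replace(self, output_dir="")).encode()).hexdigest()[:10]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    sim = doc.pop("sim", {})
    weather = sim.pop("weather", {}) if isinstance(sim, dict) else {}
    grid = doc.pop("grid", {})
    pops = tuple(tuple(p) for p in doc.pop("populations", (("pop1", 3), ("pop2", 3))))
    if isinstance(weather.get("front_lat_band"), list):
        weather["front_lat_band"] = tuple(weather["front_lat_band"])
    sim_cfg = synthetic.SimulationConfig(**sim, weather=synthetic.WeatherConfig(**weather))
    return RunConfig(populations=pops, sim=sim_cfg, grid=geolocation.GridSpec(**grid), **doc)


@dataclass
class BirdResult:
    """Everything the pipeline derives for one individual."""

    deployment: DeploymentInfo
    series: SensorSeries
    truth: synthetic.TruthRecord | None
    events: list = field(default_factory=list)
    posteriors: list = field(default_factory=list)
    median_track: pd.DataFrame | None = None
    altitudes: pd.Series | None = None
    records: pd.DataFrame | None = None
    labels: pd.Series | None = None


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig):
    """Simulate the cohort (or load tag files in real-data mode)."""
    if cfg.tag_manifest is not None:
        deployments = read_manifest(cfg.tag_manifest)
        if cfg.weather_file is None or not Path(cfg.weather_file).exists():
            raise StageError("simulate", f"weather file {cfg.weather_file!r} not found")
        import xarray as xr

        grid = xr.open_dataset(cfg.weather_file)
        base = Path(cfg.tag_manifest).parent
        birds = [
            BirdResult(d, SensorSeries.from_csv(base / d.tag_file, d.individual_id, d.population_id), None)
            for d in deployments
        ]
        return birds, grid

    grid = synthetic.simulate_weather_grid(cfg.sim)
    birds = []
    for pop, n in cfg.populations:
        for i in range(n):
            bid = f"{pop}-{i + 1:02d}"
            sim = replace(cfg.sim, seed=cfg.seed)
            series, truth = synthetic.simulate_annual_cycle(sim, bid, pop, weather=grid)
            dep = DeploymentInfo(
                bid, pop, sim.colony_lat, sim.colony_lon,
                pd.Timestamp(sim.start), pd.Timestamp(sim.end), f"tag_{bid}.csv",
            )
            birds.append(BirdResult(dep, series, truth))
    log.info("simulated %d birds over %s..%s", len(birds), cfg.sim.start, cfg.sim.end)
    return birds, grid


def stage_geolocate(cfg: RunConfig, birds, grid):
    thr = cfg.threshold()
    for b in birds:
        events = geolocation.detect_twilights(b.series.light, thr)
        events = geolocation.flag_unnatural(
            b.series.light, events, fraction=cfg.unnatural_fraction,
            dynamic_range=cfg.sim.light_max,
        )
        b.events = events
        elev = (
            cfg.threshold_elevation_deg
            if cfg.threshold_elevation_deg is not None
            else cfg.sim.light_center_deg
        )
        b.posteriors = geolocation.estimate_positions(
            events, cfg.grid, movement_sd_deg=cfg.movement_sd_deg,
            twilight_sd_minutes=cfg.twilight_sd_minutes, threshold_elevation_deg=elev,
        )
        b.median_track = geolocation.refine_event_times(
            geolocation.median_track(
                b.posteriors, events, b.deployment.colony_lat, b.deployment.colony_lon
            ),
            threshold_elevation_deg=elev,
        )
        log.info(
            "%s: %d events, %d natural", b.deployment.individual_id,
            len(events), sum(e.natural for e in events),
        )


def stage_ascents(cfg: RunConfig, birds, grid):
    colony = None
    for b in birds:
        colony = (b.deployment.colony_lat, b.deployment.colony_lon)
        pres = b.series.pressure.dropna()
        pos = geolocation.track_positions(b.median_track, pres.index, colony=colony)
        p0 = synthetic.grid_lookup(grid, "mslp", pos[:, 0], pos[:, 1], pres.index)
        b.altitudes = pd.Series(
            altimetry.pressure_to_altitude(pres.to_numpy(), p0), index=pres.index, name="altitude_m"
        )
        rows, dropped = [], 0
        for seq, r in enumerate(b.median_track.itertuples()):
            try:
                rec = altimetry.ascent_height(
                    b.altitudes, r.event_time, r.kind, threshold_m=cfg.ascent_threshold_m
                )
            except altimetry.MissingDataError:
                dropped += 1
                continue
            rows.append(
                {
                    "individual": b.deployment.individual_id,
                    "population": b.deployment.population_id,
                    "event_time": rec.event_time,
                    "kind": rec.event_type,
                    "seq": seq,
                    "natural": r.natural,
                    "lat": r.lat,
                    "lon": r.lon,
                    "altitude_at_twilight_m": rec.altitude_at_twilight_m,
                    "flight_alt": rec.baseline_altitude_m,
                    "ascent_height_m": rec.ascent_height_m,
                    "is_ascent": rec.is_ascent,
                    "phase": phases.phase_of_position(
                        r.lat, r.lon, colony[0], colony[1]
                    ),
                }
            )
        b.records = pd.DataFrame(rows)
        log.info("%s: %d ascent records (%d dropped for missing data)",
                 b.deployment.individual_id, len(rows), dropped)


def stage_behaviour(cfg: RunConfig, birds):
    for b in birds:
        b.labels = behaviour_mod.classify_behaviour(b.series.activity, b.series.pressure)


def stage_annotate(cfg: RunConfig, birds, grid):
    for b in birds:
        if b.records is None or b.records.empty:
            continue
        ann = weather_mod.annotate_weather(
            b.records[["event_time", "lat", "lon"]], grid
        ).drop(columns=["lat", "lon"])
        b.records = b.records.merge(ann, on="event_time", how="left")


def _ensemble_record_maker(cfg: RunConfig, birds, grid):
    """Returns ``make_records(seed)`` drawing one track per individual and
    re-deriving phase labels and weather covariates along it."""

    def make_records(run_seed: int) -> pd.DataFrame:
        frames = []
        for k, b in enumerate(birds):
            if b.records is None or b.records.empty:
                continue
            track = geolocation.sample_tracks(b.posteriors, 1, int(run_seed) + k)[0]
            colony = (b.deployment.colony_lat, b.deployment.colony_lon)
            df = b.records.drop(
                columns=[c for c in b.records.columns
                         if c in ("phase", "lat", "lon") or c in weather_mod.LEVEL_VARS
                         or c.startswith("d24_")],
            ).copy()
            pos = geolocation.track_positions(track, df["event_time"], colony=colony)
            df["lat"], df["lon"] = pos[:, 0], pos[:, 1]
            df["phase"] = phases.phase_of_position(pos[:, 0], pos[:, 1], colony[0], colony[1])
            ann = weather_mod.annotate_weather(df[["event_time", "lat", "lon"]], grid)
            df = df.merge(ann.drop(columns=["lat", "lon"]), on="event_time", how="left")
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    return make_records


def stage_model(cfg: RunConfig, birds, grid, spec: inference.ModelSpec = inference.ModelSpec()):
    maker = _ensemble_record_maker(cfg, birds, grid)
    return inference.run_ensemble(maker, n_runs=cfg.n_model_runs, seed=cfg.seed, spec=spec)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def summarise(birds, ensemble=None) -> dict:
    """Headline numbers of a run: per-phase ascent frequencies, dawn:dusk
    frequency ratio, per-phase median ascent heights, signed-rank test of
    non-breeding median ascent heights, and the ensemble relevance table."""
    rec = pd.concat([b.records for b in birds if b.records is not None], ignore_index=True)
    out: dict = {"n_individuals": int(rec["individual"].nunique()), "n_twilights": int(len(rec))}
    freq = rec.groupby("phase")["is_ascent"].mean()
    out["ascent_frequency"] = {k: round(float(v), 4) for k, v in freq.items()}
    kind_freq = rec.groupby("kind")["is_ascent"].mean()
    if "dusk" in kind_freq and kind_freq["dusk"] > 0:
        out["dawn_dusk_ratio"] = round(float(kind_freq["dawn"] / kind_freq["dusk"]), 3)
    out["median_ascent_height_m"] = {
        k: round(float(v), 1) for k, v in rec.groupby("phase")["ascent_height_m"].median().items()
    }
    nb = rec[rec["phase"] == "non-breeding"]
    med = nb.groupby("individual")["ascent_height_m"].median().dropna()
    if len(med) >= 5:
        v, p = inference.wilcoxon_median_ascent(med.to_numpy())
        out["wilcoxon_nonbreeding"] = {"V": v, "p": round(p, 6), "n": int(len(med))}
    if ensemble is not None:
        out["relevant_factors"] = ensemble.relevant_factors()
        out["ensemble_runs"] = int(len(ensemble.fits))
        out["ensemble_failed"] = int(ensemble.n_failed)
        means = ensemble.table.groupby("factor")["estimate"].mean()
        out["ensemble_mean_estimates"] = {k: round(float(v), 4) for k, v in means.items()}
    return out


def run_pipeline(cfg: RunConfig, through: str = "model") -> dict:
    """Run the pipeline up to (and including) ``through``; returns the
    summary dict and writes artifacts under ``cfg.output_dir``."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{cfg.config_hash()}_s{cfg.seed}"
    written: list[str] = []

    def emit(name, writer):
        path = outdir / name
        writer(path)
        written.append(str(path))
        return path

    current = "simulate"
    try:
        birds, grid = stage_simulate(cfg)
        if cfg.tag_manifest is None:
            deps = []
            for b in birds:
                emit(b.deployment.tag_file, b.series.to_csv)
                deps.append(b.deployment)
            emit(f"manifest_{tag}.yaml", lambda p: write_manifest(p, deps))
            emit(f"weather_{tag}.nc", lambda p: grid.to_netcdf(p, engine="scipy"))
            emit(
                f"truth_twilights_{tag}.csv",
                lambda p: pd.concat(
                    [b.truth.twilights.assign(individual=b.deployment.individual_id) for b in birds],
                    ignore_index=True,
                ).to_csv(p, index=False),
            )
        ensemble = None
        if last >= 1:
            current = "geolocate"
            stage_geolocate(cfg, birds, grid)
            emit(
                f"tracks_{tag}.csv",
                lambda p: pd.concat(
                    [b.median_track.assign(individual=b.deployment.individual_id) for b in birds],
                    ignore_index=True,
                ).to_csv(p, index=False),
            )
        if last >= 2:
            current = "ascents"
            stage_ascents(cfg, birds, grid)
        if last >= 3:
            current = "behaviour"
            stage_behaviour(cfg, birds)
            emit(
                f"behaviour_{tag}.csv",
                lambda p: pd.concat(
                    [b.labels.rename("label").to_frame().assign(individual=b.deployment.individual_id)
                     for b in birds]
                ).to_csv(p, index_label="timestamp"),
            )
        if last >= 4:
            current = "annotate"
            stage_annotate(cfg, birds, grid)
            emit(
                f"ascent_records_{tag}.csv",
                lambda p: pd.concat(
                    [b.records for b in birds if b.records is not None], ignore_index=True
                ).to_csv(p, index=False),
            )
        if last >= 5:
            current = "model"
            ensemble = stage_model(cfg, birds, grid)
            emit(f"ensemble_{tag}.csv", lambda p: ensemble.table.to_csv(p, index=False))
            emit(
                f"relevance_{tag}.json",
                lambda p: Path(p).write_text(json.dumps(ensemble.relevance, indent=2, sort_keys=True)),
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(current, str(exc), written) from exc

    summary = summarise(birds, ensemble) if last >= 2 else {"n_individuals": len(birds)}
    summary["config_hash"] = cfg.config_hash()
    summary["seed"] = cfg.seed
    summary["artifacts"] = sorted(Path(w).name for w in written)
    (outdir / f"summary_{tag}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
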