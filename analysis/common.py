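"""Shared configuration for the analysis scripts: a small demonstration
cohort (two colonies, three birds each) over one synthetic annual cycle."""

from pathlib import Path

from swiftascent import pipeline, synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def demo_config(seed: int = SEED) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        output_dir=str(RESULTS / "demo_run"),
        populations=(("alps", 3), ("balkans", 3)),
        sim=synthetic.SimulationConfig(seed=seed),
        n_model_runs=12,
        n_bootstrap_tracks=2000,
        seed=seed,
    )


def run_through(stage: str, cfg: pipeline.RunConfig | None = None):
    """Run the pipeline stages up to ``stage`` and return the bird results
    and weather grid (in memory; artifacts land in the run directory)."""
    cfg = cfg or demo_config()
    birds, grid = pipeline.stage_simulate(cfg)
    order = ["geolocate", "ascents", "behaviour", "annotate"]
    for s in order[: order.index(stage) + 1] if stage in order else []:
        if s == "geolocate":
            pipeline.stage_geolocate(cfg, birds, grid)
        elif s == "ascents":
            pipeline.stage_ascents(cfg, birds, grid)
        elif s == "behaviour":
            pipeline.stage_behaviour(cfg, birds)
        elif s == "annotate":
            pipeline.stage_annotate(cfg, birds, grid)
    return cfg, birds, grid
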