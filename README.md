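# swiftascent

Year-round analysis of **twilight ascents** — climbs of several hundred
metres around dawn and dusk — from multi-sensor geolocator tags on small
aerial birds such as Alpine swifts (*Apus melba*). The tags record light
and a vertical-acceleration activity score every 5 minutes and air
pressure and temperature every 30 minutes; from these alone the pipeline
reconstructs where each bird was, how high it flew, what it was doing, and
whether twilight ascents track the annual-cycle phase ("recalibration"
reasoning) or the stability of the atmosphere ("atmosphere profiling"
reasoning).

The package is aimed at movement ecologists working with archival
multi-sensor tags. Because raw tag deployments are rarely shareable, it
ships a first-class synthetic annual-cycle generator with full ground
truth, so every stage is testable end to end offline.

## The analysis chain

1. **Twilight detection** (threshold method): dawn is the last upward
   crossing of a fixed light level each morning, dusk the first downward
   crossing each evening, interpolated between 5-min samples. Abrupt light
   steps near an event (a bird entering or leaving its breeding cavity)
   mark it *unnatural*; those events get astronomically computed times
   instead.
2. **Positioning**: a grid hidden Markov model. Per natural event, the
   likelihood of each 1° cell comes from the observed-vs-predicted
   twilight-time residual; a Gaussian random walk links consecutive
   events; forward–backward smoothing yields a normalised probability map
   per event, from which median positions and bootstrap track draws
   derive.
3. **Altimetry**: the international barometric formula

   h = (T₀ / (dT/dh)) · (1 − (p_h/p₀)^((κ−1)/κ)),

   with T₀ = 288.15 K, dT/dh = 0.0065 K/m, κ = 1.235, p_h the tag
   pressure and p₀ the sea-level pressure at the interpolated position.
   The **ascent height** at a twilight is the mean of the two altitude
   samples nearest the event minus the mean altitude over 6 h before and
   after (the hour containing the event excluded); an **ascent** is a
   height ≥ 300 m.
4. **Behaviour**: flapping (high activity), resting (low activity *and*
   flat pressure trace), gliding (the rest).
5. **Phases**: breeding within 200 km of the colony, migration beyond
   200 km but north of 15° N, non-breeding residence south of 15° N —
   applied both to single positions and as posterior mass per region.
6. **Inference**: is_ascent ~ phase + twilight type + 12-h flight
   altitude + weather levels + absolute ±24-h changes of pressure,
   temperature and humidity; binomial GEE with an AR(1) working
   correlation over each individual's twilight sequence and the
   population as fixed adjustment; CIs are estimate ± 2·SE. The model is
   refitted on records re-derived from independently resampled tracks,
   and a factor counts as *relevant* only when zero is excluded from
   every run's interval.

## Worked example

```python
from swiftascent import pipeline, synthetic

cfg = pipeline.RunConfig(
    output_dir="runs/demo",
    populations=(("alps", 3), ("balkans", 3)),
    sim=synthetic.SimulationConfig(seed=1),
    n_model_runs=12, n_bootstrap_tracks=2000, seed=1,
)
summary = pipeline.run_pipeline(cfg)
print(summary["ascent_frequency"])
print(summary["dawn_dusk_ratio"])
print(summary["wilcoxon_nonbreeding"])
```

prints (seed 1):

```
{'breeding': 0.0263, 'migration': 0.077, 'non-breeding': 0.154}
1.628
{'V': 21.0, 'p': 0.015625, 'n': 6}
```

i.e. detected ascents are most frequent during the non-breeding residence
phase, about twice as frequent as during migration and far above the
breeding phase; dawn ascents outnumber dusk ascents ~1.6:1; and the
per-individual median non-breeding ascent heights are significantly
positive (signed-rank V = 21 over n = 6 birds, one-sided p ≈ 0.016).
The ensemble flags the non-breeding phase and the dawn effect as relevant
with positive signs — exactly the structure the generator put in.

The same chain is broken into narrative steps under `analysis/`
(`01_simulate.py` … `06_model.py`), each writing its tables to
`results/`. The command-line interface mirrors the stages:
`swiftascent simulate|geolocate|ascents|behaviour|annotate|model|all`.

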