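"""Barometric altitudes and the twilight-ascent statistic.

Converts tag pressure to altitude ASL against the weather grid's sea-level
pressure at the interpolated median position, then computes per-twilight
ascent heights (altitude at twilight minus the 12-h baseline) and the
300-m binary flag.  Writes results/03_ascent_summary.csv; the per-phase
ascent frequencies should recover the generated ordering
non-breeding > migration > breeding and dawn > dusk."""

import pandas as pd

from common import RESULTS, run_through


def main():
    cfg, birds, grid = run_through("ascents")
    rec = pd.concat([b.records for b in birds], ignore_index=True)
    summary = (
        rec.groupby(["phase", "kind"])
        .agg(n=("is_ascent", "size"), ascent_frequency=("is_ascent", "mean"),
             median_height_m=("ascent_height_m", "median"))
        .round(3)
        .reset_index()
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "03_ascent_summary.csv", index=False)
    print(summary.to_string(index=False))
    freq = rec.groupby("phase")["is_ascent"].mean()
    print(f"\nascent frequency ordering: non-breeding {freq['non-breeding']:.2f} > "
          f"migration {freq['migration']:.2f} > breeding {freq['breeding']:.2f}")
    kind = rec.groupby("kind")["is_ascent"].mean()
    print(f"dawn:dusk frequency ratio: {kind['dawn'] / kind['dusk']:.2f}")


if __name__ == "__main__":
    main()
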