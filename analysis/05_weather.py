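"""Annotate every twilight with weather at the interpolated position: the
6-h window's MSLP, 2-m temperature, relative humidity and 1000-mbar wind,
plus the absolute ±24-h change factors for pressure, temperature and
humidity (wind changes are excluded by design).

Writes results/05_weather_by_ascent.csv comparing covariate means between
ascent and non-ascent twilights; because the generator draws ascents
independently of weather, the standardised differences should be small."""

import numpy as np
import pandas as pd

from common import RESULTS, run_through
from swiftascent.weather import DELTA_VARS, LEVEL_VARS


def main():
    cfg, birds, grid = run_through("annotate")
    rec = pd.concat([b.records for b in birds], ignore_index=True)
    cols = list(LEVEL_VARS) + [f"d24_{w}_{v}" for v in DELTA_VARS for w in ("before", "after")]
    rows = []
    for c in cols:
        a = rec.loc[rec["is_ascent"], c]
        b_ = rec.loc[~rec["is_ascent"], c]
        pooled = rec[c].std(ddof=1)
        rows.append({"factor": c, "mean_ascent": round(a.mean(), 3),
                     "mean_no_ascent": round(b_.mean(), 3),
                     "standardised_difference": round((a.mean() - b_.mean()) / pooled, 3)})
    out = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "05_weather_by_ascent.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
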