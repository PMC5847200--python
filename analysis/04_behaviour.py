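"""Classify every 5-min interval as flapping / gliding / resting from
activity and rolling pressure variance, and score the labels against
generator truth.

Writes results/04_behaviour_confusion.csv (row-normalised confusion
matrix) and results/04_hourly_frequency.csv (hour × date frequencies of
each behaviour, the aggregation behind a season-long activity heat map)."""

import pandas as pd

from common import RESULTS, run_through
from swiftascent import behaviour


def main():
    cfg, birds, grid = run_through("behaviour")
    comps = []
    for b in birds:
        comps.append(pd.DataFrame({
            "pred": b.labels, "true": b.truth.behaviour.reindex(b.labels.index)
        }).dropna())
    comp = pd.concat(comps)
    confusion = pd.crosstab(comp["true"], comp["pred"], normalize="index").round(3)
    RESULTS.mkdir(exist_ok=True)
    confusion.to_csv(RESULTS / "04_behaviour_confusion.csv")
    print("row-normalised confusion matrix (truth in rows):")
    print(confusion.to_string())
    acc = {c: confusion.loc[c, c] for c in confusion.index}
    print(f"\nper-class accuracy: {acc}")

    hourly = behaviour.hourly_summary(pd.concat([b.labels for b in birds]))
    hourly["month"] = pd.DatetimeIndex(hourly["date"]).to_period("M").astype(str)
    compact = hourly.drop(columns=["date"]).groupby(["month", "hour"]).mean().round(3).reset_index()
    compact.to_csv(RESULTS / "04_hourly_frequency.csv", index=False)
    print(f"wrote hour-of-day x month behaviour frequencies ({len(compact)} rows)")


if __name__ == "__main__":
    main()
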