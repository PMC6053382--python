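#!/usr/bin/env python
"""Change-from-baseline maturation analysis: z-score every well x metric at
weeks 2-3 against its own week-1 epoch baseline, classify significant
increases (z > 1.96), summarise per group with the k/n (%) convention, and
compare treated vs control week-3 z-scores with one-sided rank-sum tests.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from meanet.io import read_spike_table
from meanet.maturation import cohort_zscore_table, format_proportion

OUT = Path(__file__).resolve().parents[1] / "results"
METRICS = ("n_bursting_cells", "wmfr", "event_sync", "cc_peak", "mbfr")


def main() -> None:
    wells = []
    for week in (1, 2, 3):
        path = OUT / f"spikes_week{week}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing -- run 01_simulate_cohort.py first")
        wells.extend(read_spike_table(path))

    tab = cohort_zscore_table(wells, metrics=METRICS)
    tab.to_csv(OUT / "maturation_zscores.csv", index=False)

    rows = []
    for (tp, cond, metric), sub in tab.groupby(["timepoint", "condition", "metric"]):
        k = int(sub["significant_increase"].sum())
        rows.append({"timepoint": tp, "condition": cond, "metric": metric,
                     "k": k, "n": len(sub), "proportion": format_proportion(k, len(sub)),
                     "mean_z": sub["z"].mean()})
    prop = pd.DataFrame(rows)
    prop.to_csv(OUT / "maturation_proportions.csv", index=False)

    print(f"z-scores -> {OUT / 'maturation_zscores.csv'}")
    print("\nwells with significant week-3 increase from week-1 baseline:")
    wk3 = prop[prop.timepoint == "week3"]
    for _, r in wk3.iterrows():
        print(f"  {r.condition:10s} {r.metric:18s} {r.proportion:>12s}  "
              f"mean z = {r.mean_z:6.1f}")

    print("\nglutamate vs control week-3 z (one-sided rank-sum, treated lower):")
    for metric in METRICS:
        sub = tab[(tab.timepoint == "week3") & (tab.metric == metric)]
        ctrl = sub[sub.condition == "control"]["z"]
        glut = sub[sub.condition == "glutamate"]["z"]
        if len(ctrl) and len(glut):
            p = stats.ranksums(glut, ctrl, alternative="less").pvalue
            print(f"  {metric:18s} p = {p:.3g}")


if __name__ == "__main__":
    main()
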