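#!/usr/bin/env python
"""Per-well network metrics for the simulated cohort: active electrodes,
wMFR, bursting cells, event synchronization, cross-correlation peak, and
population-burst rate (mBFR). Reads the spike tables written by
01_simulate_cohort.py and writes one tidy metrics table.
"""

from pathlib import Path

import pandas as pd

from meanet import network_metrics
from meanet.io import read_spike_table, write_metrics

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = []
    for week in (1, 2, 3):
        path = OUT / f"spikes_week{week}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing -- run 01_simulate_cohort.py first")
        for well in read_spike_table(path):
            key = (well.well_id, well.timepoint, well.condition, well.stimulation)
            records.append((key, network_metrics(well)))
    write_metrics(records, OUT / "network_metrics.csv")

    df = pd.read_csv(OUT / "network_metrics.csv")
    summary = (df.groupby(["timepoint", "condition"])
               [["n_active_electrodes", "wmfr", "event_sync", "cc_peak", "mbfr"]]
               .mean().round(3))
    print(f"{len(df)} well-recordings -> {OUT / 'network_metrics.csv'}")
    print("\ngroup means (maturation rises in control, brake under glutamate):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
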