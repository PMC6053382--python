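"""Longitudinal maturation analysis and evoked-response quantification.

Change from the week-1 baseline is expressed as a z-score: the week-1
recording is subdivided into equal epochs (10 x 30 s by default), the metric
is computed per epoch, and the later week's epoch-mean is referenced to the
week-1 epoch mean and SD. A well shows a *significant increase* when
z > 1.96. Evoked responses are summarised as a percent-of-baseline firing
time course and a peri-stimulus histogram z-scored against the 200-ms
pre-pulse baseline, averaged over pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain, StimulationSchedule, WellRecording
from .excitability import (active_trains, count_bursting_cells,
                           weighted_mean_firing_rate)
from .synchrony import detect_population_bursts, mean_cc_peak, mean_event_sync

__all__ = [
    "ZScoreResult", "Psth", "METRICS", "well_metric",
    "metric_over_epochs", "baseline_distribution", "epoch_metric_mean",
    "zscore_change", "proportion_increasing", "format_proportion",
    "percent_baseline_timecourse", "peri_stimulus_histogram",
]

Z_CRITICAL = 1.96


@dataclass
class ZScoreResult:
    well_id: str
    metric_name: str
    timepoint: str
    z: float
    significant_increase: bool

    def __post_init__(self) -> None:
        if self.significant_increase != (self.z > Z_CRITICAL):
            raise ValueError("significance flag inconsistent with z > 1.96")


@dataclass
class Psth:
    rel_bins: np.ndarray   # bin centres relative to pulse onset, s
    z_values: np.ndarray
    n_pulses: int
    flags: tuple = ()


def _metric_wmfr(well: WellRecording) -> float:
    return weighted_mean_firing_rate(well)[0]


def _metric_bursting(well: WellRecording) -> float:
    return float(count_bursting_cells(well))


def _metric_event_sync(well: WellRecording) -> float:
    return mean_event_sync(well)[0]


def _metric_cc_peak(well: WellRecording) -> float:
    return mean_cc_peak(well)[0]


def _metric_mbfr(well: WellRecording) -> float:
    return detect_population_bursts(well)[1]


#: per-well metric registry; every metric is either a per-second rate or a
#: dimensionless quantity, so epoch values are directly comparable
METRICS = {
    "wmfr": _metric_wmfr,
    "n_bursting_cells": _metric_bursting,
    "event_sync": _metric_event_sync,
    "cc_peak": _metric_cc_peak,
    "mbfr": _metric_mbfr,
}


def well_metric(well: WellRecording, metric: str) -> float:
    try:
        return METRICS[metric](well)
    except KeyError:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")


def metric_over_epochs(well: WellRecording, metric: str,
                       n_epochs: int = 10) -> np.ndarray:
    """Metric evaluated on each of ``n_epochs`` equal sub-recordings."""
    edges = np.linspace(0.0, well.duration, n_epochs + 1)
    return np.array([well_metric(well.slice(a, b), metric)
                     for a, b in zip(edges[:-1], edges[1:])])


def baseline_distribution(well_week1: WellRecording, metric: str,
                          n_epochs: int = 10, sd_floor: float = 0.01,
                          ) -> tuple[float, float]:
    """Week-1 baseline (mean, sd) of a metric over equal epochs.

    The SD is floored at ``sd_floor`` so identical epochs still yield a
    finite z. Epochs where the metric is undefined (NaN) are dropped; if
    none remain the baseline is undefined.
    """
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs for a baseline SD")
    vals = metric_over_epochs(well_week1, metric, n_epochs)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"metric {metric!r} undefined in every baseline epoch")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), max(sd, sd_floor)


def epoch_metric_mean(well: WellRecording, metric: str, n_epochs: int = 10) -> float:
    """Epoch-mean metric for a later-week recording, on the same scale as
    the baseline distribution."""
    vals = metric_over_epochs(well, metric, n_epochs)
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def zscore_change(value_at_t: float, baseline: tuple[float, float],
                  well_id: str = "W00", metric_name: str = "wmfr",
                  timepoint: str = "week3") -> ZScoreResult:
    """z = (value - baseline mean) / baseline sd; significant iff z > 1.96
    (strict, matching the printed criterion)."""
    mean, sd = baseline
    if sd <= 0:
        raise ValueError("baseline sd must be positive")
    z = (value_at_t - mean) / sd
    return ZScoreResult(well_id=well_id, metric_name=metric_name,
                        timepoint=timepoint, z=float(z),
                        significant_increase=bool(z > Z_CRITICAL))


def well_zscore(week1: WellRecording, week_t: WellRecording, metric: str,
                n_epochs: int = 10, sd_floor: float = 0.01) -> ZScoreResult:
    """Convenience: baseline from ``week1``, epoch-mean value from ``week_t``."""
    base = baseline_distribution(week1, metric, n_epochs, sd_floor)
    value = epoch_metric_mean(week_t, metric, n_epochs)
    return zscore_change(value, base, well_id=week_t.well_id,
                         metric_name=metric, timepoint=week_t.timepoint)


def proportion_increasing(results) -> tuple[int, int, float]:
    """(k, n, fraction) of wells with a significant increase."""
    results = list(results)
    n = len(results)
    if n == 0:
        raise ValueError("no z-score results to summarise")
    k = sum(r.significant_increase for r in results)
    return k, n, k / n


def format_proportion(k: int, n: int) -> str:
    """The 'k/n (xx.x%)' display convention for well proportions."""
    return f"{k}/{n} ({100.0 * k / n:.1f}%)"


def percent_baseline_timecourse(well: WellRecording, pre_window: float = 300.0,
                                bin_width: float = 60.0) -> tuple[np.ndarray, tuple]:
    """wMFR per bin as a percentage of the mean pre-stimulation wMFR.

    The baseline is the mean over the bins fully inside ``[0, pre_window)``.
    Returns ``(percent_values, flags)``; a silent baseline flags the result
    and yields NaNs.
    """
    act = active_trains(well)
    n_bins = int(np.ceil(well.duration / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for t in act:
        counts += np.histogram(t.times, bins=edges)[0]
    if not act:
        return np.full(n_bins, np.nan), ("no_active_electrodes",)
    rate = counts / bin_width / len(act)  # spikes/s/active electrode per bin
    n_pre = int(round(pre_window / bin_width))
    baseline = rate[:n_pre].mean() if n_pre else float("nan")
    if not np.isfinite(baseline) or baseline == 0:
        return np.full(n_bins, np.nan), ("silent_baseline",)
    return 100.0 * rate / baseline, ()


def peri_stimulus_histogram(well: WellRecording, sched: StimulationSchedule,
                            baseline_window: float = 0.2,
                            response_window: float = 0.6,
                            bin_width: float = 0.02,
                            sd_floor: float = 1e-6) -> Psth:
    """Pulse-aligned population activity as a z-score.

    Population spike counts (all active electrodes pooled) are binned
    relative to each pulse onset over ``[-baseline_window, response_window)``;
    each pulse is z-scored against the mean/SD of its own pre-onset baseline
    bins, then z-profiles are averaged across pulses. Pulses whose window
    would be truncated by the recording edges are dropped.
    """
    act = active_trains(well)
    spikes = (np.sort(np.concatenate([t.times for t in act]))
              if act else np.empty(0))
    n_pre = int(round(baseline_window / bin_width))
    n_post = int(round(response_window / bin_width))
    rel_edges = (np.arange(n_pre + n_post + 1) - n_pre) * bin_width
    rel_centers = rel_edges[:-1] + bin_width / 2

    profiles, flags = [], set()
    for onset in sched.pulse_onsets:
        if onset + rel_edges[0] < 0 or onset + rel_edges[-1] > well.duration:
            continue
        counts = np.histogram(spikes - onset, bins=rel_edges)[0].astype(float)
        base = counts[:n_pre]
        mu, sd = base.mean(), base.std(ddof=1) if n_pre > 1 else 0.0
        if sd <= 0:
            sd = sd_floor
            flags.add("zero_variance_baseline")
        profiles.append((counts - mu) / sd)
    if not profiles:
        return Psth(rel_bins=rel_centers, z_values=np.full(rel_centers.size, np.nan),
                    n_pulses=0, flags=("no_usable_pulses",))
    return Psth(rel_bins=rel_centers, z_values=np.mean(profiles, axis=0),
                n_pulses=len(profiles), flags=tuple(sorted(flags)))


def cohort_zscore_table(wells, metrics=("n_bursting_cells", "wmfr", "event_sync",
                                        "cc_peak", "mbfr"),
                        baseline_timepoint: str = "week1",
                        n_epochs: int = 10) -> pd.DataFrame:
    """Z-score every well x metric x later timepoint against its own week-1
    baseline; returns a tidy DataFrame."""
    by_well: dict[str, dict[str, WellRecording]] = {}
    for w in wells:
        by_well.setdefault(w.well_id, {})[w.timepoint] = w
    rows = []
    for wid, tps in sorted(by_well.items()):
        if baseline_timepoint not in tps:
            continue
        week1 = tps[baseline_timepoint]
        for tp, rec in sorted(tps.items()):
            if tp == baseline_timepoint:
                continue
            for metric in metrics:
                try:
                    r = well_zscore(week1, rec, metric, n_epochs=n_epochs)
                except ValueError:
                    continue
                rows.append({"well_id": wid, "condition": rec.condition,
                             "stimulation": rec.stimulation, "timepoint": tp,
                             "metric": metric, "z": r.z,
                             "significant_increase": r.significant_increase})
    return pd.DataFrame(rows)
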