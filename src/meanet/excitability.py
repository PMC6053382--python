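"""Excitability metrics: active-electrode classification, firing rates,
instantaneous population rate, and low-threshold rebound-burst detection.

An electrode is *active* when it fires at least 5 spikes/min over the
recording; the weighted mean firing rate (wMFR) of a well is the population
rate normalised per active electrode. A rebound burst requires 50 ms of
silence, then at least 3 spikes whose consecutive inter-spike intervals are
below 5 ms, and continues while ISIs stay within 20 ms.
"""

from __future__ import annotations

import numpy as np

from .core import BinSeries, Burst, SpikeTrain, WellRecording

ACTIVE_SPIKES_PER_MIN = 5.0


def is_active(train: SpikeTrain, spikes_per_min: float = ACTIVE_SPIKES_PER_MIN) -> bool:
    """True iff the train fires at least ``spikes_per_min`` (boundary inclusive)."""
    return train.n_spikes / (train.duration / 60.0) >= spikes_per_min


def active_trains(well: WellRecording) -> list[SpikeTrain]:
    return [t for t in well.trains if is_active(t)]


def mean_firing_rate(train: SpikeTrain) -> float:
    """mFR in spikes/s."""
    return train.n_spikes / train.duration


def weighted_mean_firing_rate(well: WellRecording) -> tuple[float, int, tuple]:
    """Well wMFR in spikes/s/active-electrode.

    Returns ``(wmfr, n_active, flags)``; a well with no active electrode
    reports 0 with a ``"no_active_electrodes"`` flag so longitudinal tables
    stay rectangular.
    """
    act = active_trains(well)
    if not act:
        return 0.0, 0, ("no_active_electrodes",)
    total = sum(t.n_spikes for t in act)
    return total / well.duration / len(act), len(act), ()


def instantaneous_wmfr(well: WellRecording, bin_width: float = 0.1) -> BinSeries:
    """100-ms-binned population rate per active electrode plus the per-bin
    count of distinct active electrodes spiking (CellCount per bin)."""
    act = active_trains(well)
    n_bins = int(np.ceil(well.duration / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    cellcount = np.zeros(n_bins)
    for t in act:
        h, _ = np.histogram(t.times, bins=edges)
        counts += h
        cellcount += h > 0
    n_active = len(act)
    wmfr = counts / n_active if n_active else counts
    return BinSeries(bin_width=bin_width, values_wmfr=wmfr,
                     values_cellcount=cellcount, n_active=n_active)


def detect_unit_bursts(train: SpikeTrain, silence: float = 0.050,
                       init_n: int = 3, init_isi: float = 0.005,
                       max_isi: float = 0.020) -> list[Burst]:
    """Low-threshold rebound bursts.

    A burst starts at spike ``i`` if ``i`` is preceded by at least ``silence``
    seconds without spikes (the first spike of a recording counts as preceded
    by silence) and the ``init_n`` spikes from ``i`` have consecutive ISIs
    strictly below ``init_isi``; it then extends while ISIs are at most
    ``max_isi``. Bursts are maximal and non-overlapping; scanning resumes
    after each burst end.
    """
    t = train.times
    n = t.size
    bursts: list[Burst] = []
    i = 0
    while i < n:
        gap = t[i] - t[i - 1] if i > 0 else np.inf
        if (gap >= silence and i + init_n - 1 < n
                and np.all(np.diff(t[i:i + init_n]) < init_isi)):
            j = i + init_n - 1
            while j + 1 < n and t[j + 1] - t[j] <= max_isi:
                j += 1
            bursts.append(Burst(start=float(t[i]), stop=float(t[j]),
                                n_spikes=j - i + 1, kind="unit"))
            i = j + 1
        else:
            i += 1
    return bursts


def unit_burst_rate(train: SpikeTrain, per: str = "min", **kwargs) -> float:
    """mBR: unit bursts per minute (``per="s"`` for per-second)."""
    n = len(detect_unit_bursts(train, **kwargs))
    scale = 60.0 if per == "min" else 1.0
    return n / train.duration * scale


def count_bursting_cells(well: WellRecording, **kwargs) -> int:
    """Number of units/electrodes showing at least one rebound burst."""
    return sum(bool(detect_unit_bursts(t, **kwargs)) for t in well.trains)
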