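"""Pairwise and population synchrony.

Three measures are implemented:

* *Event synchronization* (Quian Quiroga-style): the number of
  quasi-simultaneous spike pairs between two trains under a pairwise
  adaptive coincidence window, normalised to be symmetric and equal to 1
  for identical trains and 0 for fully asynchronous ones.
* *Cross-correlogram peak*: the lag-0 value of the [-10, 10] s, 100-ms-bin
  coincidence histogram normalised by ``sqrt(N_x * N_y)`` spike counts.
* *Population bursts*: well-wide co-activation events (>= 30% of active
  electrodes co-firing within a 100-ms bin at supra-threshold wMFR), with
  start/stop boundaries from the 50% point of the cumulative histogram of
  instantaneous wMFR x cell count. mBFR is their rate in events/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import Burst, SpikeTrain, WellRecording
from .excitability import active_trains, instantaneous_wmfr

__all__ = [
    "event_synchronization",
    "mean_event_sync",
    "CrossCorrelogram",
    "cross_correlogram",
    "cross_correlation_peak",
    "mean_cc_peak",
    "detect_population_bursts",
]


def _neighbor_half_isi(times: np.ndarray) -> np.ndarray:
    """Half the smaller neighbouring ISI per spike (inf at the boundaries of
    a single-spike train)."""
    if times.size < 2:
        return np.full(times.size, np.inf)
    isi = np.diff(times)
    prev = np.concatenate(([np.inf], isi))
    nxt = np.concatenate((isi, [np.inf]))
    return 0.5 * np.minimum(prev, nxt)


def event_synchronization(x: SpikeTrain, y: SpikeTrain,
                          tau_mode: str = "adaptive",
                          tau_max: float = 0.05) -> float:
    """Symmetric event synchronization Q in [0, 1].

    The coincidence window for the pair (i, j) is half the minimum of the
    four neighbouring ISIs, capped at ``tau_max`` (``tau_mode="fixed"`` uses
    ``tau_max`` throughout). Spikes at exactly equal times count 1/2 towards
    each direction, which yields Q = 1 for identical trains.
    """
    tx, ty = x.times, y.times
    if tx.size == 0 or ty.size == 0:
        raise ValueError("event synchronization is undefined for empty trains; "
                         "filter to active electrodes first")
    if tau_mode == "adaptive":
        hx = _neighbor_half_isi(tx)
        hy = _neighbor_half_isi(ty)
    elif tau_mode == "fixed":
        hx = np.full(tx.size, np.inf)
        hy = np.full(ty.size, np.inf)
    else:
        raise ValueError(f"unknown tau_mode {tau_mode!r}")

    # only pairs within tau_max can coincide, so gather candidates by
    # bisection instead of forming the full pairwise matrix
    lo = np.searchsorted(ty, tx - tau_max, side="left")
    hi = np.searchsorted(ty, tx + tau_max, side="right")
    counts = hi - lo
    i_idx = np.repeat(np.arange(tx.size), counts)
    j_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) \
        if i_idx.size else np.empty(0, dtype=int)
    d = tx[i_idx] - ty[j_idx]
    tau = np.minimum(np.minimum(hx[i_idx], hy[j_idx]), tau_max)
    cxy = np.count_nonzero((d > 0) & (d <= tau))    # x follows y within tau
    cyx = np.count_nonzero((d < 0) & (-d <= tau))   # y follows x within tau
    c_eq = np.count_nonzero(d == 0.0)               # 1/2 to each direction
    q = (cxy + cyx + c_eq) / np.sqrt(tx.size * ty.size)
    return float(min(max(q, 0.0), 1.0))


def mean_event_sync(well: WellRecording, **kwargs) -> tuple[float, tuple]:
    """Unweighted mean Q over all unordered pairs of active electrodes.

    Returns ``(value, flags)``; fewer than two active electrodes yields
    ``nan`` with a flag.
    """
    act = active_trains(well)
    if len(act) < 2:
        return float("nan"), ("lt2_active_electrodes",)
    qs = [event_synchronization(a, b, **kwargs) for a, b in combinations(act, 2)]
    return float(np.mean(qs)), ()


@dataclass
class CrossCorrelogram:
    lags: np.ndarray        # bin centres, s
    bin_width: float
    values: np.ndarray      # coincidence counts / sqrt(Nx * Ny)

    @property
    def lag0_value(self) -> float:
        return float(self.values[self.values.size // 2])


def cross_correlogram(x: SpikeTrain, y: SpikeTrain, lag_range: float = 10.0,
                      bin_width: float = 0.1) -> CrossCorrelogram:
    """Normalised coincidence histogram of ``t_y - t_x`` over [-range, range].

    Bins are centred on integer multiples of ``bin_width`` (the lag-0 bin is
    ``[-bin/2, bin/2)``) and counts are divided by ``sqrt(N_x * N_y)``, so an
    identical sparse train gives exactly 1.0 at lag 0.
    """
    tx, ty = x.times, y.times
    if tx.size == 0 or ty.size == 0:
        raise ValueError("cross-correlogram is undefined for empty trains")
    k = int(round(lag_range / bin_width))
    centers = np.arange(-k, k + 1) * bin_width
    edges = np.concatenate((centers - bin_width / 2, [centers[-1] + bin_width / 2]))
    # gather pairwise differences inside the lag range by bisection
    i0 = np.searchsorted(ty, tx + edges[0], side="left")
    i1 = np.searchsorted(ty, tx + edges[-1], side="left")
    n_per = i1 - i0
    ref = np.repeat(tx, n_per)
    j_idx = np.concatenate([np.arange(a, b) for a, b in zip(i0, i1)]) \
        if ref.size else np.empty(0, dtype=int)
    counts = np.histogram(ty[j_idx] - ref, bins=edges)[0].astype(float)
    values = counts / np.sqrt(tx.size * ty.size)
    return CrossCorrelogram(lags=centers, bin_width=bin_width, values=values)


def cross_correlation_peak(x: SpikeTrain, y: SpikeTrain,
                           bin_width: float = 0.1, **kwargs) -> float:
    """Value of the normalised cross-correlogram at lag 0.

    Computed directly as the count of pairs with ``t_y - t_x`` in the
    centred lag-0 bin ``[-bin/2, bin/2)`` over ``sqrt(N_x * N_y)``; equal to
    ``cross_correlogram(...).lag0_value`` without building the histogram.
    """
    tx, ty = x.times, y.times
    if tx.size == 0 or ty.size == 0:
        raise ValueError("cross-correlogram is undefined for empty trains")
    n = (np.searchsorted(ty, tx + bin_width / 2, side="left")
         - np.searchsorted(ty, tx - bin_width / 2, side="left")).sum()
    return float(n / np.sqrt(tx.size * ty.size))


def mean_cc_peak(well: WellRecording, **kwargs) -> tuple[float, tuple]:
    """Mean lag-0 value over all unordered pairs of active electrodes."""
    act = active_trains(well)
    if len(act) < 2:
        return float("nan"), ("lt2_active_electrodes",)
    vals = [cross_correlation_peak(a, b, **kwargs) for a, b in combinations(act, 2)]
    return float(np.mean(vals)), ()


def detect_population_bursts(well: WellRecording, frac_active: float = 0.30,
                             wmfr_min: float = 0.5, bin_width: float = 0.1,
                             cdf_level: float = 0.5,
                             nonzero_only: bool = True,
                             ) -> tuple[list[Burst], float, float, tuple]:
    """Population-burst detection.

    A candidate bin has at least ``frac_active`` of the active electrodes
    spiking together *and* instantaneous wMFR above ``wmfr_min``
    (spikes/bin/active electrode). Burst boundaries come from expanding each
    candidate bin while ``P = wMFR x CellCount`` stays at or above the
    ``cdf_level`` point of the empirical cumulative histogram of P (over
    nonzero-activity bins by default); runs separated by less than one bin
    merge. Returns ``(bursts, mbfr, mean_duration, flags)`` with mBFR in
    events/s over the whole recording.
    """
    bs = instantaneous_wmfr(well, bin_width=bin_width)
    if bs.n_active == 0:
        return [], 0.0, float("nan"), ("no_active_electrodes",)

    candidate = (bs.values_cellcount >= frac_active * bs.n_active) & \
                (bs.values_wmfr > wmfr_min)
    p = bs.values_wmfr * bs.values_cellcount
    pool = p[p > 0] if nonzero_only else p
    if not candidate.any() or pool.size == 0:
        return [], 0.0, float("nan"), ()
    # smallest P at which the empirical CDF reaches cdf_level
    threshold = float(np.quantile(pool, cdf_level, method="inverted_cdf"))

    above = p >= threshold
    # maximal runs of supra-threshold bins; a run is a burst iff it contains
    # a candidate bin (runs are merged by construction: any sub-bin gap in
    # `above` separates them, < 1 bin gaps cannot occur on a bin grid)
    bursts: list[Burst] = []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)  # exclusive
    act = active_trains(well)
    for b0, b1 in zip(starts, stops):
        if not candidate[b0:b1].any():
            continue
        t0, t1 = b0 * bin_width, b1 * bin_width
        n_spikes = int(sum(np.count_nonzero((t.times >= t0) & (t.times < t1))
                           for t in act))
        bursts.append(Burst(start=float(t0), stop=float(t1),
                            n_spikes=n_spikes, kind="population"))
    mbfr = len(bursts) / well.duration
    mean_dur = float(np.mean([b.duration for b in bursts])) if bursts else float("nan")
    return bursts, mbfr, mean_dur, ()
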