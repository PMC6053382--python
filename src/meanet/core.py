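"""Domain types for multi-well MEA network analysis.

All times are seconds, zero-based at recording start; every binning operation
uses half-open bins ``[t, t + dt)`` so a spike is never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "SpikeTrain",
    "WellRecording",
    "BinSeries",
    "Burst",
    "NetworkMetrics",
    "StimulationSchedule",
    "QpcrSample",
    "QpcrResult",
    "TARGET_GENES",
    "HOUSEKEEPING_GENES",
]

TARGET_GENES = ("NR2A", "NR2B", "BDNF", "RAB3A")
HOUSEKEEPING_GENES = ("GAPDH", "HPRT1")


@dataclass
class RawRecording:
    """Multi-channel extracellular voltage trace.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_channels, n_samples)``, in microvolts. The
        acquisition gain (1200x in the reference setup) is applied upstream;
        samples here are already physical units.
    sampling_rate
        Hz; 12 500 for the Maestro-style acquisition emulated here.
    """

    samples: np.ndarray
    sampling_rate: float = 12500.0
    channel_ids: Sequence[str] = ()
    well_id: str = "W00"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float32))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw samples contain non-finite voltages")
        if not self.channel_ids:
            self.channel_ids = [f"E{i:02d}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class SpikeTrain:
    """Sorted spike times for one electrode/unit within one recording."""

    times: np.ndarray
    electrode_id: str = "E00"
    unit_id: str = "mua"
    duration: float = 300.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.times.size:
            if not np.all(np.isfinite(self.times)):
                raise ValueError(f"spike times contain NaN/inf on {self.electrode_id}")
            if np.any(np.diff(self.times) < 0):
                raise ValueError(f"spike times not sorted on {self.electrode_id}")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError(
                    f"spike times outside [0, {self.duration}] on {self.electrode_id}"
                )

    @classmethod
    def from_times(
        cls,
        times: Sequence[float],
        *,
        electrode_id: str = "E00",
        unit_id: str = "mua",
        duration: float = 300.0,
        sample_period: float = 1.0 / 12500.0,
    ) -> "SpikeTrain":
        """Build a train, deduplicating spikes that collide within one sample."""
        t = np.sort(np.asarray(times, dtype=float).ravel())
        if t.size:
            keep = np.ones(t.size, dtype=bool)
            keep[1:] = np.diff(t) >= sample_period
            t = t[keep]
        return cls(t, electrode_id=electrode_id, unit_id=unit_id, duration=duration)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def key(self) -> tuple:
        return (self.electrode_id, self.unit_id)

    def slice(self, t0: float, t1: float) -> "SpikeTrain":
        """Sub-train on ``[t0, t1)`` re-referenced to ``t0``."""
        sel = self.times[(self.times >= t0) & (self.times < t1)] - t0
        return SpikeTrain(sel, electrode_id=self.electrode_id,
                          unit_id=self.unit_id, duration=t1 - t0)


@dataclass
class WellRecording:
    """All spike trains of one well at one timepoint.

    ``condition`` is the treatment arm (``control`` or ``glutamate``) and
    ``stimulation`` the FES protocol (``NoStim``, ``LFS``, ``DCS``, ``LFS_DCS``).
    """

    trains: list
    well_id: str = "W00"
    timepoint: str = "week1"
    condition: str = "control"
    stimulation: str = "NoStim"
    duration: float = 300.0

    def __post_init__(self) -> None:
        keys = [t.key() for t in self.trains]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate (electrode, unit) keys in well {self.well_id}")
        for t in self.trains:
            if abs(t.duration - self.duration) > 1e-9:
                raise ValueError(
                    f"train {t.key()} duration {t.duration} != well duration {self.duration}"
                )

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains)

    def slice(self, t0: float, t1: float) -> "WellRecording":
        return WellRecording(
            [t.slice(t0, t1) for t in self.trains],
            well_id=self.well_id, timepoint=self.timepoint,
            condition=self.condition, stimulation=self.stimulation,
            duration=t1 - t0,
        )


@dataclass
class BinSeries:
    """100-ms (by default) binned population activity for one well.

    ``values_wmfr`` is spikes per bin per active electrode (the instantaneous
    wMFR); ``values_cellcount`` the number of distinct active electrodes with
    at least one spike in the bin.
    """

    bin_width: float
    values_wmfr: np.ndarray
    values_cellcount: np.ndarray
    n_active: int

    def __post_init__(self) -> None:
        self.values_wmfr = np.asarray(self.values_wmfr, dtype=float)
        self.values_cellcount = np.asarray(self.values_cellcount, dtype=float)
        if self.values_wmfr.shape != self.values_cellcount.shape:
            raise ValueError("wMFR and cell-count series differ in length")
        if np.any(self.values_wmfr < 0) or np.any(self.values_cellcount < 0):
            raise ValueError("bin series values must be non-negative")
        if self.n_active and np.any(self.values_cellcount > self.n_active):
            raise ValueError("cell count per bin exceeds number of active electrodes")

    @property
    def n_bins(self) -> int:
        return int(self.values_wmfr.size)

    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width


@dataclass(frozen=True)
class Burst:
    """A detected burst, either per-unit (rebound) or population-wide."""

    start: float
    stop: float
    n_spikes: int
    kind: str = "unit"  # "unit" | "population"

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"burst stop {self.stop} before start {self.start}")
        if self.kind == "unit" and self.n_spikes < 3:
            raise ValueError("a unit burst has at least 3 spikes")

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class NetworkMetrics:
    """Per-well excitability and synchrony summary."""

    n_active_electrodes: int = 0
    wmfr: float = 0.0                 # spikes / s / active electrode
    n_bursting_cells: int = 0
    event_sync: float = float("nan")  # in [0, 1]
    cc_peak: float = float("nan")     # >= 0
    mbfr: float = 0.0                 # population-burst events / s
    mean_burst_duration: float = float("nan")  # s
    flags: tuple = ()

    FIELDS = ("n_active_electrodes", "wmfr", "n_bursting_cells", "event_sync",
              "cc_peak", "mbfr", "mean_burst_duration")

    def __post_init__(self) -> None:
        if self.n_active_electrodes < 0 or self.wmfr < 0 or self.mbfr < 0:
            raise ValueError("network metrics must be non-negative")
        if np.isfinite(self.event_sync) and not (0.0 <= self.event_sync <= 1.0 + 1e-12):
            raise ValueError(f"event_sync {self.event_sync} outside [0, 1]")


@dataclass
class StimulationSchedule:
    """Pulse onsets for an LFS/DCS session (delivery hardware not modelled)."""

    pulse_onsets: np.ndarray
    pulse_duration: float = 0.2
    mode: str = "LFS"
    amplitude_uA: float = 10.0  # metadata only

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float).ravel()
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.pulse_onsets.size and np.any(np.diff(self.pulse_onsets) < 0):
            raise ValueError("pulse onsets must be sorted")

    @classmethod
    def lfs(cls, start: float = 0.0, rate_hz: float = 0.1,
            n_pulses: int = 90, pulse_duration: float = 0.2) -> "StimulationSchedule":
        """0.1-Hz low-frequency schedule (15 min = 90 pulses by default)."""
        onsets = start + np.arange(n_pulses) / rate_hz
        return cls(onsets, pulse_duration=pulse_duration, mode="LFS")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets.size)


@dataclass
class QpcrSample:
    """Replicate CT values for one sample x gene."""

    sample_id: str
    group: str
    gene: str
    ct_values: np.ndarray

    def __post_init__(self) -> None:
        self.ct_values = np.asarray(self.ct_values, dtype=float).ravel()
        finite = self.ct_values[np.isfinite(self.ct_values)]
        if finite.size == 0:
            raise ValueError(
                f"sample {self.sample_id} gene {self.gene}: no finite CT value"
            )
        if np.any(finite <= 0) or np.any(finite > 45):
            raise ValueError(
                f"sample {self.sample_id} gene {self.gene}: CT outside (0, 45]"
            )


@dataclass
class QpcrResult:
    """ddCT outcome for one gene x group.

    ``rq = 2**(-ddct)``; ``signed_fold`` is the display convention that maps
    down-regulation to a negative fold (``-1/rq`` when ``rq < 1``), so its
    magnitude is always >= 1.
    """

    gene: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    signed_fold: float
    sem: float = float("nan")
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("RQ must be positive")
        if abs(self.rq - 2.0 ** (-self.delta_delta_ct)) > 1e-9 * max(1.0, self.rq):
            raise ValueError("rq inconsistent with 2^(-ddCT)")


def signed_fold(rq: float) -> float:
    """Fig-style fold display: ``rq`` if >= 1, else ``-1/rq``."""
    if rq <= 0:
        raise ValueError("RQ must be positive")
    return rq if rq >= 1.0 else -1.0 / rq
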