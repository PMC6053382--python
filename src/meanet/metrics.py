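"""Per-well metric assembly: one call from a spike-train well to the full
excitability + synchrony summary."""

from __future__ import annotations

from .core import NetworkMetrics, WellRecording
from .excitability import (active_trains, count_bursting_cells,
                           weighted_mean_firing_rate)
from .synchrony import detect_population_bursts, mean_cc_peak, mean_event_sync

__all__ = ["network_metrics"]


def network_metrics(well: WellRecording) -> NetworkMetrics:
    """Compute the per-well summary used throughout the longitudinal analysis."""
    wmfr, n_active, f1 = weighted_mean_firing_rate(well)
    es, f2 = mean_event_sync(well)
    cc, f3 = mean_cc_peak(well)
    bursts, mbfr, mean_dur, f4 = detect_population_bursts(well)
    return NetworkMetrics(
        n_active_electrodes=n_active,
        wmfr=wmfr,
        n_bursting_cells=count_bursting_cells(well),
        event_sync=es,
        cc_peak=cc,
        mbfr=mbfr,
        mean_burst_duration=mean_dur,
        flags=tuple(dict.fromkeys(f1 + f2 + f3 + f4)),
    )
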