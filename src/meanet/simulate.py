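"""Synthetic MEA data generator.

Emulates the statistical structure the analysis assumes: 12-well plates of
64 electrodes whose firing, bursting and synchrony grow from week 1 to
week 3; an acute-glutamate condition that multiplies the week-over-week
parameter increments by a brake factor ``gamma < 1``; raw-trace rendering
with biphasic spike templates whose peak-to-valley width and amplitude
follow the printed normal distributions (553 +/- 150 us, 37 +/- 12 uV) over
Gaussian noise; evoked stimulation responses (suppression during a pulse,
rebound after); and qPCR CT tables with programmed log2 fold effects.

All randomness flows from a single integer seed through named SeedSequence
substreams (per condition, well, week, electrode), so adding wells never
perturbs existing ones and identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (HOUSEKEEPING_GENES, TARGET_GENES, QpcrSample, RawRecording,
                   SpikeTrain, StimulationSchedule, WellRecording)

__all__ = ["SimConfig", "simulate_well", "simulate_cohort", "render_raw",
           "simulate_stim_session", "simulate_qpcr", "rng_for"]

_CONDITIONS = ("control", "glutamate")
_STIMS = ("NoStim", "LFS", "DCS", "LFS_DCS")


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Named substream: independent generator for a (seed, keys...) path."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(keys)))


@dataclass
class SimConfig:
    """Generator parameters; weekly schedules are ``{week: value}`` maps.

    The weekly defaults encode a maturing culture: the active-electrode
    fraction, tonic rate, unit-burst rate, population-event rate and
    synchrony participation all grow week over week. The glutamate brake
    ``gamma`` scales the increments from the week-1 baseline.
    """

    n_wells: int = 12
    n_electrodes: int = 64
    duration: float = 300.0
    sampling_rate: float = 12500.0
    frac_active: dict = field(default_factory=lambda: {1: 0.25, 2: 0.45, 3: 0.65})
    tonic_rate: dict = field(default_factory=lambda: {1: 0.5, 2: 1.5, 3: 3.0})  # Hz
    unit_burst_rate: dict = field(default_factory=lambda: {1: 1.0, 2: 3.0, 3: 6.0})  # /min
    pop_event_rate: dict = field(default_factory=lambda: {1: 2.0, 2: 6.0, 3: 10.0})  # /min
    p_sync: dict = field(default_factory=lambda: {1: 0.30, 2: 0.50, 3: 0.70})
    sync_jitter: float = 0.010           # s
    inactive_rate: float = 1.0 / 60.0    # Hz, below the 5 spikes/min threshold
    glutamate_growth_factor: float = 0.3  # gamma
    stim_recovery: dict = field(default_factory=lambda: {
        "NoStim": 0.0, "LFS": 0.9, "DCS": 0.6, "LFS_DCS": 0.1})
    well_effect_sigma: float = 0.15      # lognormal random-effect scale
    # raw-trace rendering
    waveform_width_mean: float = 553.0   # us, peak-to-valley
    waveform_width_sd: float = 150.0
    waveform_amp_mean: float = 37.0      # uV, peak-to-valley
    waveform_amp_sd: float = 12.0
    noise_rms: float = 3.0               # uV
    # evoked response
    stim_suppression: float = 0.8        # fraction of spikes removed in-pulse
    stim_rebound_gain: float = 2.0       # rate multiplier after pulse offset
    stim_rebound_window: float = 0.3     # s
    # qPCR
    qpcr_replicate_sd: float = 0.2       # cycles
    qpcr_housekeeping_sd: float = 0.15   # cycles
    qpcr_base_ct: dict = field(default_factory=lambda: {
        "NR2A": 26.0, "NR2B": 26.5, "BDNF": 24.0, "RAB3A": 23.0,
        "GAPDH": 18.0, "HPRT1": 22.0})
    qpcr_effects: dict = field(default_factory=lambda: {
        # log2 fold vs the media-only control, emulating an ~8-fold NR2A
        # down-regulation after acute glutamate with no stimulation
        ("glutamate", "NoStim"): {"NR2A": -3.104, "NR2B": -1.5,
                                  "BDNF": -2.0, "RAB3A": -1.6},
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_active", "p_sync"):
            if any(not 0 <= v <= 1 for v in getattr(self, name).values()):
                raise ValueError(f"{name} values must be in [0, 1]")
        if not 0 <= self.glutamate_growth_factor <= 1:
            raise ValueError("glutamate_growth_factor must be in [0, 1]")
        for name in ("tonic_rate", "unit_burst_rate", "pop_event_rate"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} values must be non-negative")


def _weekly(cfg: SimConfig, sched: dict, week: int, condition: str,
            stimulation: str = "NoStim") -> float:
    """Weekly parameter with the glutamate brake on increments.

    Under glutamate, the increment from the week-1 baseline is scaled by
    ``gamma``; stimulation protocols applied after week 2 recover a fraction
    of the suppressed increment at week 3 (emulating LFS/DCS rescue).
    """
    target = sched[week]
    if condition == "control" or week == 1:
        return target
    base = sched[1]
    gamma = cfg.glutamate_growth_factor
    if week >= 3 and stimulation in cfg.stim_recovery:
        gamma = gamma + (1 - gamma) * cfg.stim_recovery[stimulation]
    return base + gamma * (target - base)


def _burst_spikes(rng: np.random.Generator, start: float, n_min: int = 3,
                  n_max: int = 8) -> np.ndarray:
    """Spike times of one rebound burst satisfying the detector's criteria:
    first ISIs tight (< 5 ms), continuation ISIs within (5, 19) ms."""
    n = int(rng.integers(n_min, n_max + 1))
    init = rng.uniform(0.001, 0.0045, size=2)
    cont = rng.uniform(0.0055, 0.019, size=max(n - 3, 0))
    return start + np.concatenate(([0.0], np.cumsum(np.concatenate((init, cont)))))[:n]


def _assemble_electrode(tonic: np.ndarray, bursts: list[np.ndarray],
                        duration: float, sample_period: float,
                        silence: float = 0.055) -> np.ndarray:
    """Merge tonic and burst spikes, clearing the pre-burst silence window.

    Bursts are kept in time order; a burst whose silence window would overlap
    the previous burst is dropped, and tonic spikes inside
    ``[start - silence, stop]`` of any kept burst are removed so that every
    generated burst still satisfies the rebound-burst criteria.
    """
    kept = []
    last_stop = -np.inf
    for b in sorted(bursts, key=lambda a: a[0]):
        if b[0] - silence <= last_stop or b[-1] >= duration:
            continue
        kept.append(b)
        last_stop = b[-1]
    for b in kept:
        tonic = tonic[(tonic < b[0] - silence) | (tonic > b[-1] + 1e-9)]
    times = np.sort(np.concatenate([tonic] + kept)) if kept else np.sort(tonic)
    if times.size:
        keep = np.ones(times.size, dtype=bool)
        keep[1:] = np.diff(times) >= sample_period
        times = times[keep]
    return times[(times >= 0) & (times < duration)]


def simulate_well(cfg: SimConfig, week: int, condition: str = "control",
                  seed: int | None = None, well_index: int = 0,
                  stimulation: str = "NoStim", well_id: str | None = None,
                  rate_effect: float = 1.0, return_truth: bool = False):
    """Simulate one well at one timepoint.

    Each electrode is active with probability ``frac_active(week)``; active
    electrodes emit tonic Poisson spikes, rebound bursts (criteria enforced
    at generation) and population events in which they participate with
    probability ``p_sync(week)`` with a small Gaussian jitter.

    ``rate_effect`` is a per-well multiplicative random effect supplied by
    :func:`simulate_cohort`. With ``return_truth`` the per-electrode
    generated unit-burst start times are returned as well.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    seed = cfg.seed if seed is None else seed
    cond_idx = _CONDITIONS.index(condition) * len(_STIMS) + _STIMS.index(stimulation)
    p_act = _weekly(cfg, cfg.frac_active, week, condition, stimulation)
    tonic = rate_effect * _weekly(cfg, cfg.tonic_rate, week, condition, stimulation)
    br = rate_effect * _weekly(cfg, cfg.unit_burst_rate, week, condition, stimulation) / 60.0
    pr = rate_effect * _weekly(cfg, cfg.pop_event_rate, week, condition, stimulation) / 60.0
    psync = _weekly(cfg, cfg.p_sync, week, condition, stimulation)
    dt = 1.0 / cfg.sampling_rate

    well_rng = rng_for(seed, cond_idx, well_index, week, cfg.n_electrodes)
    n_pop = well_rng.poisson(pr * cfg.duration)
    pop_events = np.sort(well_rng.uniform(0, cfg.duration - 0.3, size=n_pop))

    trains, truth = [], {}
    for e in range(cfg.n_electrodes):
        rng = rng_for(seed, cond_idx, well_index, week, e)
        eid = f"E{e:02d}"
        if rng.random() >= p_act:
            n = rng.poisson(cfg.inactive_rate * cfg.duration)
            t = np.sort(rng.uniform(0, cfg.duration, size=n))
            trains.append(SpikeTrain(t, electrode_id=eid, duration=cfg.duration))
            continue
        n_tonic = rng.poisson(tonic * cfg.duration)
        tonic_t = np.sort(rng.uniform(0, cfg.duration, size=n_tonic))
        n_b = rng.poisson(br * cfg.duration)
        unit_starts = np.sort(rng.uniform(0.1, cfg.duration - 0.3, size=n_b))
        # space unit bursts >= 0.5 s apart so silence windows never collide
        if unit_starts.size > 1:
            keep = np.concatenate(([True], np.diff(unit_starts) >= 0.5))
            unit_starts = unit_starts[keep]
        bursts = [_burst_spikes(rng, s) for s in unit_starts]
        pop_mask = rng.random(pop_events.size) < psync
        pop_bursts = [
            _burst_spikes(rng, ev + rng.normal(0.0, cfg.sync_jitter), n_max=5)
            for ev in pop_events[pop_mask]
        ]
        times = _assemble_electrode(tonic_t, bursts + pop_bursts,
                                    cfg.duration, dt)
        trains.append(SpikeTrain(times, electrode_id=eid, duration=cfg.duration))
        truth[eid] = unit_starts
    well = WellRecording(trains, well_id=well_id or f"W{well_index:02d}",
                         timepoint=f"week{week}", condition=condition,
                         stimulation=stimulation, duration=cfg.duration)
    return (well, truth) if return_truth else well


def simulate_cohort(cfg: SimConfig, weeks=(1, 2, 3),
                    conditions=(("control", "NoStim"), ("glutamate", "NoStim")),
                    seed: int | None = None):
    """Longitudinal multi-well cohort with persistent per-well random effects.

    Returns ``(wells, truth)`` where ``truth`` is a tidy DataFrame with the
    effective generative parameters of every well x week.
    """
    seed = cfg.seed if seed is None else seed
    wells, rows = [], []
    for condition, stim in conditions:
        cond_idx = _CONDITIONS.index(condition) * len(_STIMS) + _STIMS.index(stim)
        for w in range(cfg.n_wells):
            eff = float(np.exp(rng_for(seed, cond_idx, w, 999, 0)
                               .normal(0.0, cfg.well_effect_sigma)))
            wid = f"{condition[:4]}_{stim}_W{w:02d}"
            for week in weeks:
                wells.append(simulate_well(
                    cfg, week, condition, seed=seed, well_index=w,
                    stimulation=stim, well_id=wid, rate_effect=eff))
                rows.append({
                    "well_id": wid, "condition": condition, "stimulation": stim,
                    "week": week, "rate_effect": eff,
                    "frac_active": _weekly(cfg, cfg.frac_active, week, condition, stim),
                    "tonic_rate": eff * _weekly(cfg, cfg.tonic_rate, week, condition, stim),
                    "unit_burst_rate": eff * _weekly(cfg, cfg.unit_burst_rate, week, condition, stim),
                    "pop_event_rate": eff * _weekly(cfg, cfg.pop_event_rate, week, condition, stim),
                    "p_sync": _weekly(cfg, cfg.p_sync, week, condition, stim),
                })
    return wells, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raw-trace rendering
# ---------------------------------------------------------------------------

def _unit_template() -> tuple[np.ndarray, np.ndarray]:
    """Canonical biphasic shape on a dense normalised time grid.

    Valley-dominant (valley ~0.85 of the peak-to-valley excursion, typical
    of somatic extracellular spikes), rescaled so the minimum sits at s = 0
    and max - min = 1. The lobe widths and the overall time stretch (1.030)
    were calibrated once against the full measurement chain -- 12.5 kHz
    sampling, zero-phase 200-3000 Hz bandpass, 6x RMS detection and
    max-minus-min metrology at 3 uV RMS noise -- so that the chain recovers
    the programmed peak-to-valley width and amplitude without systematic
    bias (the printed reference statistics are themselves post-chain
    measurements).
    """
    stretch = 1.030
    s = np.linspace(-2.5, 4.0, 2601)
    v = -0.85 * np.exp(-(s ** 2) / (2 * 0.22 ** 2)) \
        + 0.18 * np.exp(-((s - 1.0) ** 2) / (2 * 0.60 ** 2))
    imin, imax = np.argmin(v), np.argmax(v)
    p2v = v[imax] - v[imin]
    s0, s1 = s[imin], s[imax]
    return stretch * (s - s0) / (s1 - s0), v / p2v


_TEMPLATE_S, _TEMPLATE_V = _unit_template()


def spike_template(amplitude: float, width_us: float, sampling_rate: float,
                   ) -> tuple[np.ndarray, int]:
    """Sampled biphasic template with programmed peak-to-valley amplitude
    (uV) and width (us). Returns ``(samples, valley_index)``."""
    w = width_us * 1e-6
    t0, t1 = _TEMPLATE_S[0] * w, _TEMPLATE_S[-1] * w
    n0 = int(np.floor(t0 * sampling_rate))
    n1 = int(np.ceil(t1 * sampling_rate))
    tt = np.arange(n0, n1 + 1) / sampling_rate
    samples = amplitude * np.interp(tt / w, _TEMPLATE_S, _TEMPLATE_V)
    return samples, -n0


def render_raw(well: WellRecording, cfg: SimConfig, seed: int | None = None,
               ) -> RawRecording:
    """Render a spike-train well into a raw voltage trace.

    Gaussian noise at ``noise_rms`` plus, at every spike time, a biphasic
    template with truncated-normal peak-to-valley amplitude and width;
    overlapping templates sum.
    """
    seed = cfg.seed if seed is None else seed
    fs = cfg.sampling_rate
    n_samples = int(round(well.duration * fs))
    traces = np.empty((len(well.trains), n_samples), dtype=np.float32)
    for ch, train in enumerate(well.trains):
        rng = rng_for(seed, 7001, ch)
        tr = rng.normal(0.0, cfg.noise_rms, size=n_samples)
        for t in train.times:
            amp = rng.normal(cfg.waveform_amp_mean, cfg.waveform_amp_sd)
            wid = rng.normal(cfg.waveform_width_mean, cfg.waveform_width_sd)
            amp = max(amp, 5.0)
            wid = max(wid, 150.0)
            tmpl, valley = spike_template(amp, wid, fs)
            i0 = int(round(t * fs)) - valley
            j0, j1 = max(i0, 0), min(i0 + tmpl.size, n_samples)
            if j1 > j0:
                tr[j0:j1] += tmpl[j0 - i0:j1 - i0]
        traces[ch] = tr
    return RawRecording(traces, sampling_rate=fs,
                        channel_ids=[t.electrode_id for t in well.trains],
                        well_id=well.well_id)


# ---------------------------------------------------------------------------
# stimulation sessions and qPCR
# ---------------------------------------------------------------------------

def simulate_stim_session(well: WellRecording, sched: StimulationSchedule,
                          cfg: SimConfig, seed: int | None = None,
                          ) -> WellRecording:
    """Overlay an evoked response on an existing well.

    During each pulse, spikes are thinned by ``stim_suppression``; for
    ``stim_rebound_window`` seconds after pulse offset the firing rate is
    scaled by ``stim_rebound_gain`` (extra Poisson spikes at the electrode's
    own mean rate).
    """
    seed = cfg.seed if seed is None else seed
    onsets = sched.pulse_onsets
    offs = onsets + sched.pulse_duration
    out = []
    for ch, train in enumerate(well.trains):
        rng = rng_for(seed, 8001, ch)
        t = train.times
        in_pulse = np.zeros(t.size, dtype=bool)
        for on, off in zip(onsets, offs):
            in_pulse |= (t >= on) & (t < off)
        keep = ~in_pulse | (rng.random(t.size) >= cfg.stim_suppression)
        t = t[keep]
        extra_rate = (cfg.stim_rebound_gain - 1.0) * train.n_spikes / train.duration
        extras = []
        if extra_rate > 0:
            for off in offs:
                hi = min(off + cfg.stim_rebound_window, well.duration)
                n = rng.poisson(extra_rate * (hi - off))
                extras.append(rng.uniform(off, hi, size=n))
        if extras:
            t = np.concatenate([t] + extras)
        out.append(SpikeTrain.from_times(
            t, electrode_id=train.electrode_id, unit_id=train.unit_id,
            duration=well.duration, sample_period=1.0 / cfg.sampling_rate))
    return WellRecording(out, well_id=well.well_id, timepoint=well.timepoint,
                         condition=well.condition, stimulation=sched.mode,
                         duration=well.duration)


def simulate_qpcr(cfg: SimConfig, groups=None, n_repeats: int = 6,
                  n_replicates: int = 3, seed: int | None = None,
                  ) -> list[QpcrSample]:
    """Synthetic CT table: housekeeping genes ~ Normal(base, 0.15); target
    CT = base - log2fold(gene, group) + replicate noise; triplicates per
    sample, ``n_repeats`` samples per group."""
    seed = cfg.seed if seed is None else seed
    if groups is None:
        groups = [("control", "NoStim")] + sorted(cfg.qpcr_effects)
    samples = []
    for g_idx, (condition, stim) in enumerate(groups):
        label = f"{condition}_{stim}"
        effects = cfg.qpcr_effects.get((condition, stim), {})
        for r in range(n_repeats):
            rng = rng_for(seed, 9001, g_idx, r)
            sid = f"{label}_S{r:02d}"
            for gene in TARGET_GENES:
                mu = cfg.qpcr_base_ct[gene] - effects.get(gene, 0.0)
                cts = mu + rng.normal(0.0, cfg.qpcr_replicate_sd, size=n_replicates)
                samples.append(QpcrSample(sid, label, gene, cts))
            for gene in HOUSEKEEPING_GENES:
                cts = rng.normal(cfg.qpcr_base_ct[gene], cfg.qpcr_housekeeping_sd,
                                 size=n_replicates)
                samples.append(QpcrSample(sid, label, gene, cts))
    return samples
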