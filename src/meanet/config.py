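"""Parameter bundles and YAML round-tripping.

Every numeric parameter of the pipeline lives in one of two dataclasses:
:class:`AnalysisParams` (detection and metric parameters, defaults matching
the reference acquisition/analysis chain) and :class:`~.simulate.SimConfig`
(generator parameters). ``load_params``/``save_params`` serialise both to a
single YAML document; explicit keyword overrides win over file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = ["AnalysisParams", "load_params", "save_params"]


@dataclass
class AnalysisParams:
    """Detection + metric parameters (units in comments)."""

    # preprocessing
    bandpass_low: float = 200.0        # Hz
    bandpass_high: float = 3000.0      # Hz
    filter_order: int = 2              # per pass, zero-phase
    threshold_k: float = 6.0           # x noise RMS
    refractory: float = 0.001          # s
    waveform_pre: float = 0.0008       # s
    waveform_post: float = 0.0016      # s
    robust_noise: bool = False
    # excitability
    active_spikes_per_min: float = 5.0
    burst_silence: float = 0.050       # s
    burst_init_n: int = 3
    burst_init_isi: float = 0.005      # s
    burst_max_isi: float = 0.020       # s
    # synchrony
    es_tau_max: float = 0.05           # s, adaptive-window cap
    cc_lag_range: float = 10.0         # s
    cc_bin: float = 0.1                # s
    pop_frac_active: float = 0.30
    pop_wmfr_min: float = 0.5          # spikes/bin/active electrode
    pop_bin: float = 0.1               # s
    pop_cdf_level: float = 0.5
    # maturation
    n_epochs: int = 10
    sd_floor: float = 0.01
    z_critical: float = 1.96
    # evoked response
    psth_baseline: float = 0.2         # s
    psth_response: float = 0.6         # s
    psth_bin: float = 0.02             # s
    timecourse_pre: float = 300.0      # s
    timecourse_bin: float = 60.0       # s


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {("|".join(map(str, k)) if isinstance(k, tuple) else k): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _restore_keys(d: dict, tuple_keys: bool = False) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(k, str) and "|" in k:
            k = tuple(k.split("|"))
        elif isinstance(k, str) and k.isdigit():
            k = int(k)
        out[k] = v
    return out


def save_params(path, analysis: AnalysisParams | None = None,
                sim: SimConfig | None = None) -> None:
    doc = {"analysis": _to_plain(analysis or AnalysisParams()),
           "simulate": _to_plain(sim or SimConfig())}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_params(path=None, **overrides) -> tuple[AnalysisParams, SimConfig]:
    """Load both parameter bundles from YAML; ``overrides`` (keyed by field
    name) win over file values, file values over defaults."""
    a_kw, s_kw = {}, {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        a_kw.update(doc.get("analysis", {}))
        s_kw.update(doc.get("simulate", {}))
    a_fields = {f.name for f in dataclasses.fields(AnalysisParams)}
    s_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for k, v in overrides.items():
        if k in a_fields:
            a_kw[k] = v
        elif k in s_fields:
            s_kw[k] = v
        else:
            raise KeyError(f"unknown parameter {k!r}")
    for name in ("frac_active", "tonic_rate", "unit_burst_rate",
                 "pop_event_rate", "p_sync", "stim_recovery", "qpcr_base_ct"):
        if name in s_kw and isinstance(s_kw[name], dict):
            s_kw[name] = _restore_keys(s_kw[name])
    if "qpcr_effects" in s_kw and isinstance(s_kw["qpcr_effects"], dict):
        s_kw["qpcr_effects"] = _restore_keys(s_kw["qpcr_effects"])
    return AnalysisParams(**a_kw), SimConfig(**s_kw)
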