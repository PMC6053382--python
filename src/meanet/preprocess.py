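"""Raw-trace preprocessing: bandpass filtering, threshold spike detection,
waveform metrology and optional PCA-based unit sorting.

Detection follows the classical extracellular chain: zero-phase Butterworth
bandpass (200-3000 Hz), a threshold at 6x the RMS of the filtered trace, and
negative-going (valley-dominant) crossings aligned to the local minimum.
Peak-to-valley amplitude and width are measured on the cut waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import RawRecording, SpikeTrain

__all__ = [
    "Waveform",
    "bandpass_filter",
    "estimate_noise_rms",
    "detect_spikes",
    "detect_well",
    "measure_waveform",
    "sort_units",
]


@dataclass
class Waveform:
    """A cut spike waveform centred on its detection alignment (the valley)."""

    samples: np.ndarray        # uV
    sample_period: float       # s
    amplitude_p2v: float = float("nan")  # uV
    width_p2v: float = float("nan")      # us


def bandpass_filter(raw: RawRecording, low: float = 200.0, high: float = 3000.0,
                    order: int = 2) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass, per channel."""
    nyq = raw.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=raw.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    return RawRecording(filtered, sampling_rate=raw.sampling_rate,
                        channel_ids=list(raw.channel_ids), well_id=raw.well_id,
                        t0=raw.t0)


def estimate_noise_rms(trace: np.ndarray, robust: bool = False) -> float:
    """Noise scale of a (zero-mean) filtered trace in uV.

    ``robust=True`` uses the median-absolute-deviation estimate
    ``MAD / 0.6745``, which is insensitive to spike contamination.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("cannot estimate noise on an empty trace")
    if robust:
        return float(np.median(np.abs(trace - np.median(trace))) / 0.6745)
    return float(np.sqrt(np.mean(trace ** 2)))


def detect_spikes(trace: np.ndarray, sampling_rate: float, k: float = 6.0,
                  refractory: float = 0.001,
                  window: tuple[float, float] = (0.0008, 0.0016),
                  robust_noise: bool = False, bidirectional: bool = False,
                  ) -> tuple[SpikeTrain, list[Waveform]]:
    """Threshold detection on a bandpass-filtered single-channel trace.

    Events are negative-going crossings of ``-k * noise_rms`` (optionally
    also positive-going with ``bidirectional``), aligned to the local
    minimum within the refractory window; a waveform of ``window[0]`` s
    before and ``window[1]`` s after the alignment is cut. Events too close
    to the trace edges are dropped.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    pre = int(round(window[0] * sampling_rate))
    post = int(round(window[1] * sampling_rate))
    if pre + post >= trace.size:
        raise ValueError("waveform window longer than trace")
    dead = max(1, int(round(refractory * sampling_rate)))
    thr = k * estimate_noise_rms(trace, robust=robust_noise)

    exceed = trace < -thr
    if bidirectional:
        exceed |= trace > thr
    crossings = np.flatnonzero(exceed[1:] & ~exceed[:-1]) + 1
    if exceed[0]:
        crossings = np.concatenate(([0], crossings))

    times, waveforms = [], []
    last_align = -np.inf
    for c in crossings:
        if c <= last_align + dead:
            continue
        seg = trace[c:c + dead + 1]
        align = c + int(np.argmin(seg))
        if align - pre < 0 or align + post >= trace.size:
            continue
        if align <= last_align + dead:
            continue
        last_align = align
        times.append(align / sampling_rate)
        waveforms.append(Waveform(samples=trace[align - pre:align + post + 1].copy(),
                                  sample_period=1.0 / sampling_rate))
    train = SpikeTrain(np.asarray(times), duration=trace.size / sampling_rate)
    return train, waveforms


def measure_waveform(w: Waveform) -> tuple[float, float]:
    """Peak-to-valley amplitude (uV) and width (us) of a cut waveform.

    Amplitude is ``max - min``; width the absolute time between the two
    extrema. A constant waveform has no defined width.
    """
    s = np.asarray(w.samples, dtype=float)
    imin, imax = int(np.argmin(s)), int(np.argmax(s))
    amp = float(s[imax] - s[imin])
    if amp == 0.0:
        raise ValueError("constant waveform: peak-to-valley width undefined")
    width_us = abs(imax - imin) * w.sample_period * 1e6
    w.amplitude_p2v, w.width_p2v = amp, width_us
    return amp, width_us


def detect_well(raw: RawRecording, k: float = 6.0, **kwargs):
    """Run filtering + detection + metrology over every channel of a well.

    Returns ``(trains, waveforms_per_channel)`` with per-channel
    :class:`SpikeTrain` objects carrying the channel ids.
    """
    filtered = bandpass_filter(raw)
    trains, all_wf = [], []
    for ch, cid in enumerate(filtered.channel_ids):
        train, wfs = detect_spikes(filtered.samples[ch], filtered.sampling_rate,
                                   k=k, **kwargs)
        train.electrode_id = cid
        for w in wfs:
            measure_waveform(w)
        trains.append(train)
        all_wf.append(wfs)
    return trains, all_wf


def sort_units(waveforms, max_units: int = 3, n_components: int = 3,
               seed: int = 0, min_silhouette: float = 0.5) -> np.ndarray:
    """Optional spike sorting: PCA projection + centroid clustering.

    Projects waveforms on the first 2-3 principal components and clusters in
    PC space; the number of clusters (capped at ``max_units``) is chosen by
    the silhouette criterion, falling back to a single multi-unit cluster
    when separation is poor. With fewer than 20 waveforms a single "mua"
    label is returned with a warning.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    X = np.asarray([w.samples for w in waveforms], dtype=float)
    n = X.shape[0]
    if n < 20:
        warnings.warn(f"only {n} waveforms: skipping sorting, returning 'mua'")
        return np.zeros(max(n, 0), dtype=int)
    if np.allclose(X, X[0], atol=1e-12):  # degenerate: identical waveforms
        return np.zeros(n, dtype=int)

    n_pc = min(n_components, X.shape[1], n)
    pcs = PCA(n_components=n_pc, random_state=seed).fit_transform(X)
    best_labels = np.zeros(n, dtype=int)
    best_score = -np.inf
    for n_clusters in range(2, max_units + 1):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(pcs, km.labels_)
        if score > best_score:
            best_score, best_labels = score, km.labels_
    if best_score < min_silhouette:
        return np.zeros(n, dtype=int)
    return best_labels
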