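# Methods

This note documents the models and numerical choices behind `meanet`: what
each analysis stage computes, the parameters that matter with their units
and defaults, what the synthetic generator does and does not emulate, and
the open design points that were settled here.

Time is in seconds, zero-based at recording start. Every binned quantity
uses half-open bins `[t, t + dt)` so spikes on bin edges are counted once.

## Spike detection and waveform metrology

Raw traces (µV, 12.5 kHz) are filtered per channel with a zero-phase
(forward–backward) Butterworth bandpass, 200–3000 Hz, order 2 per pass.
Zero-phase filtering preserves spike timing; order and phase handling are
our choices, stated here because the acquisition convention only fixes the
band.

Detection thresholds each channel at `k × RMS` of the filtered trace with
`k = 6`. For zero-mean noise the RMS and the standard deviation coincide,
which resolves the ambiguity in the phrase "6× standard deviation RMS"; an
MAD-based robust estimator (`MAD/0.6745`) is available by flag for
heavily spiking channels. Only negative-going crossings are detected by
default (extracellular somatic spikes are valley-dominant); events align to
the local minimum within a 1-ms dead time, and a waveform of 0.8 ms before
/ 1.6 ms after the valley is cut (wide enough for the expected ~550-µs
peak-to-valley width plus margin). Peak-to-valley amplitude is
`max − min` of the cut waveform; width is `|t(max) − t(min)|` in µs.

Unit sorting is optional and off by default. "KNN clustering" of waveforms
is not a defined clustering algorithm, so sorting is implemented as PCA
projection (2–3 components) plus centroid (k-means) clustering with the
cluster count chosen by the silhouette criterion, capped at 3; below a 0.5
silhouette, or with fewer than 20 waveforms, everything stays one
multi-unit ("mua") cluster.

## Excitability

* **Active electrode**: at least 5 spikes/min over the recording
  (boundary inclusive). Population metrics use only active electrodes.
* **wMFR**: total spikes of active electrodes / duration / n_active,
  i.e. spikes·s⁻¹·active-electrode⁻¹. A well with no active electrode
  reports wMFR = 0 with an explicit flag rather than NaN so longitudinal
  tables stay rectangular.
* **Instantaneous wMFR**: 100-ms bins, spikes per bin per active
  electrode, together with the per-bin count of distinct active
  electrodes spiking (cell count per bin).
* **Rebound bursts**: a burst starts at a spike preceded by ≥ 50 ms of
  silence (the first spike of a recording counts as silence-preceded —
  pre-recording history is unobservable) whose next two inter-spike
  intervals are each strictly below 5 ms; it extends while ISIs stay
  ≤ 20 ms. Comparisons are strict/inclusive exactly as the criteria are
  worded ("lower than" 5 ms, maximum "set to" 20 ms, "at least" for the
  activity rule). The silence requirement applies to the burst's first
  spike, not to the whole 3-spike window — the wording is ambiguous and
  this is the conventional reading of silence-gated burst detectors.

## Synchrony

**Event synchronization.** For trains x, y with spike counts mₓ, m_y, the
coincidence window of a pair (i, j) is half the minimum of the four
neighbouring ISIs, capped at τ_max = 50 ms (the citation's adaptive window;
the cap matches the 100-ms analysis scale; a fixed-window mode exists).
c(x|y) counts spikes of x that follow a spike of y within the window;
pairs at exactly equal times count ½ to each direction. Then

    Q = (c(x|y) + c(y|x)) / sqrt(mₓ · m_y),  clipped to [0, 1],

which is symmetric by construction, 1 for identical trains and 0 for
trains with no quasi-coincident pairs. Empty trains are a caller error —
the well-level mean is taken over all unordered pairs of *active*
electrodes, and is flagged undefined below two active electrodes.

**Cross-correlogram.** Counts of `t_y − t_x` over lags [−10, 10] s in
100-ms bins centred on integer multiples of the bin width (so the lag-0
bin is [−50, 50) ms and "the value at lag 0" is well defined), divided by
`sqrt(Nₓ · N_y)`. "Train length" is read as spike count, which makes the
identical sparse train normalise to exactly 1 at lag 0. The well metric is
the lag-0 value averaged over active pairs; a direct counting path
computes the peak without building the histogram.

**Population bursts.** A candidate 100-ms bin has (1) at least 30 % of
active electrodes spiking in the bin and (2) instantaneous wMFR above
0.5 spikes/bin/electrode. Boundaries come from P(t) = instantaneous wMFR ×
cell count per bin: the start/stop threshold is the smallest P at which
the empirical CDF of P reaches 50 %, computed over nonzero-activity bins
(over all bins an inactive-dominated recording would drive the threshold
to zero; an all-bins option exists). Cell count enters as a raw count, not
a fraction — the choice only rescales P and thus the threshold, not the
ordering of crossings. Candidate bins expand while P stays at or above the
threshold; runs separated by less than one bin merge; each merged run is
one burst. mBFR is bursts per second over the whole recording (per-minute
display available).

## Maturation z-scores

The change of a well metric from its week-1 baseline is
`z = (value − mean₁) / sd₁`, with a significant increase when z > 1.96
(strict inequality). How a single well's week-1 SD was obtained is the
central interpretive decision of this module: here the week-1 recording is
subdivided into 10 equal 30-s epochs, the metric is computed per epoch,
and mean/SD are taken across epochs (SD floored at a configurable ε,
default 0.01, so identical epochs still yield finite z). The later week's
value is the epoch mean computed the same way, so epoch length never
enters the numerator; all registry metrics are per-second rates or
dimensionless. Group summaries report `k/n (%)` of wells with a
significant increase.

Evoked responses: the percent-of-baseline time course is wMFR per 1-min
bin divided by the mean wMFR of the 5-min pre-stimulation epoch (silent
baselines flagged, not divided by); the peri-stimulus histogram bins
pooled active-electrode spike counts relative to each pulse onset
(defaults: 20-ms bins, 200-ms baseline, 600-ms response window), z-scores
each pulse against its own pre-onset baseline bins (SD floor ε with flag on
zero variance), and averages z-profiles across pulses. Pulses whose
windows would be truncated by the recording edges are dropped, not padded.

## ΔΔCT quantification

Replicate CTs are averaged per sample (NaN replicates dropped; a warning
fires when the replicate range exceeds 0.5 cycles). ΔCT subtracts the
arithmetic mean of the housekeeping CTs — for two references this is the
geometric mean of their expression, the standard dual-control choice.
ΔΔCT references the calibrator (media-only) group's mean ΔCT, RQ =
2^(−ΔΔCT) with efficiency fixed at 2, and the display convention maps
RQ < 1 to −1/RQ so fold magnitude is always ≥ 1. The SEM reported with a
group fold is that of the per-sample signed folds. The calibrator group's
own fold is exactly +1 by construction.

## The synthetic generator

The generator reproduces the statistical structure the analysis assumes;
it is not a biophysical model. Per electrode, activity is a superposition
of (i) homogeneous Poisson tonic spikes, (ii) rebound bursts from a Poisson
event process whose bursts satisfy the detector's criteria by construction
(≥ 50 ms enforced pre-silence, 3–8 spikes, onset ISIs ~ U(1, 4.5) ms,
continuation ISIs ~ U(5.5, 19) ms; conflicting tonic spikes are cleared
from the silence window and burst span), and (iii) population events —
shared burst triggers in which each active electrode participates with
probability p_sync, jittered by N(0, 10 ms). Shared triggers with
Bernoulli participation are the simplest mechanism that makes the
30 %-co-activation criterion controllable. Spikes colliding within one
sample period are merged.

Weekly schedules encode maturation (defaults, weeks 1→3): active fraction
0.25/0.45/0.65, tonic rate 0.5/1.5/3.0 Hz, unit bursts 1/3/6 per min,
population events 2/6/10 per min, p_sync 0.30/0.50/0.70. These are chosen
as representative of maturing MEA cultures — sparse, weakly coupled
activity in week 1 growing to dense synchronous bursting by week 3 — and
fixed once; inactive electrodes fire at 1 spike/min, safely below the
activity threshold. The glutamate arm multiplies week-over-week increments
from the week-1 baseline by γ (default 0.3): maturation is braked, not
silenced, matching an acute excitotoxic insult that slows network
formation. Stimulation arms recover a fraction of the suppressed increment
at week 3 (LFS 0.9, DCS 0.6, LFS/DCS 0.1), emulating rescue by single
protocols and its absence under the combination. Per-well lognormal rate
effects (σ = 0.15) persist across weeks. All randomness descends from one
seed through named `SeedSequence` substreams (condition, well, week,
electrode), so adding wells or weeks never perturbs existing ones and
identical seeds are bit-identical.

Raw rendering adds, at each spike time, a biphasic valley-dominant
template scaled to a peak-to-valley amplitude ~ N(37, 12) µV (truncated at
5 µV) and width ~ N(553, 150) µs (truncated at 150 µs), summed over
Gaussian noise at 3 µV RMS. The canonical template (valley 0.85 / rebound
peak 0.18 of the unit excursion; lobe σ of 0.22 and 0.60 of the
valley-to-peak interval; time stretch 1.030) was calibrated once against
the full measurement chain so that the chain's systematic terms — small
spikes censored by the 6σ threshold, noise inflating the measured extrema,
filter attenuation and sampling quantisation — cancel, and the measured
means reproduce the programmed means. The reference width/amplitude
statistics are themselves post-detection measurements, so the generator's
contract is on what the standard chain measures.

Stimulation sessions thin spikes inside each 200-ms pulse by the
suppression fraction (default 0.8) and add Poisson spikes at
(rebound_gain − 1) × the electrode's own mean rate for 300 ms after pulse
offset (default gain 2), producing the suppression-then-rebound PSTH
profile. CT tables draw housekeeping CTs ~ N(base, 0.15) and target CTs at
`base − log2fold(gene, group)` with 0.2-cycle replicate noise, triplicates
per sample and 6 samples per group; the default effect set encodes a
~−8.6-fold NR2A down-regulation (log₂ −3.104) with milder NR2B/BDNF/RAB3A
suppression in the glutamate/NoStim group.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: electrode-to-electrode gain/impedance
variation, non-stationary drift within a recording, bursty non-Poisson
tonic statistics, spike-waveform diversity beyond one template family,
overlapping-spike superposition artefacts at high rates, LFP content below
200 Hz, stimulation artefacts, and any biology linking the
electrophysiology to the gene-expression effects (the two are programmed
independently).

## Problem sizes and numerical choices

Analysis drivers default to 6 wells per condition × 3 weeks at 64
electrodes and 300 s; the waveform-metrology runs use 8 electrodes × 120 s
at 12.5 kHz (~1000 detected spikes), sizes at which every stage's
statistics are already stable. Degenerate inputs are contracts, not
crashes: empty trains are rejected where a measure is undefined
(event sync, correlograms) and flagged where a longitudinal table needs a
value (wMFR, mBFR, baselines). Detection on an all-zero trace returns an
empty train (threshold 0 is never strictly crossed). Ties in k-means are
fixed by the seeded initialisation; the CDF threshold uses the
`inverted_cdf` quantile so it is always an observed value of P.

## Known limitations

The epoch-based baseline makes week-1 SD depend on epoch count (10 × 30 s
here); metrics that are counts over a window (bursting cells) are noisier
per epoch than rates. Event synchronization is clipped to [0, 1] — with
the adaptive window and near-duplicate spike times the raw statistic can
exceed 1 in pathological cases. The efficiency-corrected ΔΔCT variant
(per-gene amplification efficiencies) is out of scope, as are
vendor-format readers, spike-distance synchrony measures, alternative
burst detectors, and omnibus group statistics beyond the rank-sum
comparisons used in the drivers.
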