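# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `chewevents`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and pipeline assumptions

The detectors assume a multi-channel surface-EMG recording of the
temporalis muscles (bilateral eyeglasses-style montage, 256 Hz per channel
in all defaults) in which chewing cycles appear as short activity bursts
recurring quasi-periodically at 0.94–2.17 Hz during eating, against a
baseline whose rectified amplitude is approximately half-normal. Amplitude
units are arbitrary throughout: every threshold is either estimated from
data (`θC`) or grid-searched (`θ0`, `θ1`), never assumed in physical units.

Times are seconds relative to recording start; sample `i` maps to `i/fs`
exactly. All intervals are half-open `[start, end)`, which makes overlap
durations additive without double-counting boundary samples.

## Pre-processing

Notch (50 Hz, second-order IIR, Q = 30) and high-pass (20 Hz, fourth-order
Butterworth), both applied forward–backward. Zero phase matters here: a
causal filter would delay every detected onset by the group delay and bias
the start/end timing errors that the package is designed to measure. Edge
transients are handled by scipy's default odd-reflection padding; tests
that quantify stop-band attenuation therefore measure the steady-state
portion. Filter family, order and Q are package defaults — the pipeline
contract only fixes the corner frequencies and the rectification.

## Chewing-cycle detection

The windowed below/above count (window `w = 100` samples = 0.4 s, no
larger than one chewing cycle) is computed with integer prefix sums, an
exact incremental update that the test suite checks bit-for-bit against a
per-window recount. Conventions that the algorithm's informal description
leaves open, fixed as follows:

- the window of length `w` splits into halves of `w/2` samples; samples
  equal to `θC` count in neither half, so the index lies in `[0, w]`;
- an onset is a *strict* local maximum of the index series exceeding
  `θP·w` (plateaus are not peaks); the peak threshold is interpreted as a
  fraction of `w` since `θP ∈ [0, 1]`;
- the onset time is the peak's window start plus `w/2`: the index is
  maximal when the contraction begins at the window centre;
- after an accepted onset the scan skips `round(t_interval · fs)` samples,
  so onsets are at least the refractory distance apart.

`θC = μ + 3σ` uses the population standard deviation of pre-processed
baseline amplitude. "Baseline" is operationalised as *all samples outside
reference eating events*, pooled over all training participants and
channels; with half-normal baseline noise the resulting threshold sits
above ~99.7% of baseline samples.

## Chewing-segment detection

Segments are found by an iterative scan of the declarative start/end rules
(first onset with `f ≥ θ0` starts a segment; the onset `C[j_end+θ0−1]`
with `f[j_end] = θ0` and `f[j_end+θ0−1] = 1` ends it). Two degenerate
cases are fixed by convention:

- onset counting uses the closed window `[C[j], C[j]+w0]`, so `f ≥ 1`
  always holds;
- if the onset list ends while a segment is open (the end rule never
  fires), the segment closes at the last onset.

A structural consequence of the *exact-equality* end rule is worth noting:
on onset lists with stragglers (e.g. sporadic non-chewing onsets after an
event), the isolation condition `f[j_end+θ0−1] = 1` can be postponed for a
long time at particular `θ0` values, extending a segment far past the true
event tail. Total covered time is therefore **not** monotone in `θ0` in
general; it is monotone on clean quasi-periodic onset runs separated by
silence, and the property test asserts exactly that regime. On confounded
data the behaviour instead shows up (correctly) as a poor grid-search score
for the affected `(w0, θ0)` combinations.

## Top-down baselines

The threshold detector computes EMG work (sum of rectified samples) per
sliding window (`s1 = 256` samples = 1 s step) and records a segment start
on an upward `θ1` crossing and an end on a downward one; crossings are
paired greedily in time order, an end without an open start is dropped,
and a start left open at the recording end closes at the last evaluated
window.

The ocSVM detector cuts each channel into non-overlapping `w2`-sample
windows and classifies each window with a one-class SVM (RBF kernel)
trained on eating-labelled windows only (windows lying entirely inside a
reference event, pooled over channels and training participants). The
per-window feature set — mean, standard deviation, maximum, EMG work,
fraction of samples above `θC`, spectral centroid, and band powers
20–60 Hz and 60–120 Hz, standardised with training-set statistics — is a
declared package default behind a swappable extractor interface; the
original feature inventory for this baseline is not public. Useful RBF
widths sit near the 1/n_features scale of standardised inputs; much larger
`γ` memorises the training windows and the `ν` outlier bound stops
tracking. Because decisions are per window, every detected boundary is an
integer multiple of `w2` samples — the structural reason this baseline's
timing errors are bounded below by the window quantisation.

Both baselines feed the same fusion and gap-elimination stages as the
bottom-up detector.

## Evaluation

Retrieval metrics pool durations (`T_gt`, `T_ret`, `T_tp`) over the
recordings being scored; timing errors are per detected event (distance to
the *nearest* reference boundary, so unmatched false events contribute
large errors by design) and undefined — flagged, not zero — when there are
no detections or no reference events. Standard deviations are reported
across folds for LOPO summaries and across events within a single run;
both are exposed.

Grid search iterates combinations in the given key/value order and breaks
ties at the performance points by the first combination encountered. The
canonical benchmark grids list values conservative-first (largest `w0`,
highest `θ0` first), so on a saturated F1 surface ties resolve to the most
selective parameter set — the analogue of the one-standard-error rule in
cross-validated model selection, chosen because permissive winners of F1
ties admit rare short false events that F1 barely registers but timing
errors punish severely.

LOPO folds re-estimate everything that depends on training data (`θC`,
ocSVM models, grid-search points) from the held-in participants only.
Folds whose training union contains no eating events are flagged and
excluded from summaries.

## Synthetic generator

The generator emulates the structure of free-living bilateral temporalis
recordings: Gaussian baseline noise (σ = 1, the amplitude unit), one
Hann-enveloped band-limited (20–120 Hz) burst of 0.3 s per chewing cycle,
50 Hz hum (amplitude 0.5), slow sinusoidal baseline wander (amplitude 2),
within-meal pauses (30–120 s, i.e. shorter than `t_gap`), and
teeth-grinding confounders in non-eating time (2–4 aperiodic activations,
0.7–2 s apart). Channels share the chew schedule with < 30 ms
inter-channel jitter and independent noise/carrier — a bilateral montage
records the same mastication with electrode-specific noise.

Parameter rationale:

- **Event durations** are drawn log-uniformly over 54 s–35.8 min, the
  range reported for free-living eating occasions; the log-uniform mean
  (~9.5 min) matches the reported mean occasion length, where a uniform
  draw would triple it. The 12 h dataset template additionally resamples
  schedules until each participant's eating fraction falls in 4–8%,
  bracketing the reported 5.8% eating share of free-living time.
- **Chew burst amplitude** (`burst_snr = 15` × baseline σ) was calibrated
  once against the generator's own chew-recovery statistics: with
  default detector parameters the onset detector recovers 91–96% of
  scheduled chews across the whole 0.94–2.17 Hz rate range, i.e. high but
  not saturated. Dry-electrode temporalis bursts during chewing are
  realistically an order of magnitude above the baseline floor.
- **Grinding amplitude** (0.2 × chew amplitude, i.e. a 3σ peak sitting at
  the `μ+3σ` burst threshold) encodes that grinding shows substantially
  lower EMG work than chewing: activations are only marginally
  detectable, producing occasional spurious onsets that penalise
  permissive `(w0, θ0)` choices without overwhelming the detector.
- **Journal annotations** jitter the chew-accurate event bounds by the
  logging imprecision and round to the 1-minute resolution of a paper
  activity log, staying within ±`annotation_jitter` (60 s) of truth.

What the generator does **not** model: motion artifacts and electrode
displacement, non-stationary baseline power (the noise floor is
statistically identical in eating and non-eating time), food-texture
dependent burst amplitudes, swallowing/speech activity, and circadian
behaviour structure. One visible consequence: the EMG-work threshold
baseline — which fails on real free-living data because non-eating
activity also produces EMG work — performs *well* on these benchmarks,
since a stationary noise floor makes a global work threshold informative.
Passing synthetic benchmarks therefore demonstrates correctness of the
pipeline and the qualitative bottom-up vs. windowed-classifier ranking
(timing above all), not free-living detection performance.

## Benchmark problem sizes

Two canonical conditions are fixed in `chewevents.benchmark`:

- **single**: one 2 h, 2-channel recording with 3 events (the default
  `SynthConfig`); `θC` estimated from the recording's own non-eating
  portion, `(w0, θ0)` grid-searched over {10, 7, 5, 3} s × {8, 6, 4, 3, 2}.
- **lopo**: ten 1 h participants, 2 events each (54–500 s, log-uniform),
  LOPO-evaluated for all three detectors; ocSVM uses `w2 = 2560` samples
  (10 s), `γ ∈ {0.1, 0.5, 2}`, `ν ∈ {0.05, 0.1, 0.2}`; the threshold
  grid scales `θ1` by the median per-window work because amplitude units
  are arbitrary.

One-hour participants keep the benchmark desk-scale while preserving the
realistic eating/non-eating imbalance; all reported quantities are
cross-fold means at the PX/PS/PE points.

## Known limitations

- The exact-equality end rule's non-monotone pathologies (above) are
  inherited from the segmentation contract, not smoothed over.
- The ocSVM feature set is a stand-in; conclusions about that baseline are
  conditional on it (it is deliberately isolated behind
  `WindowFeatureExtractor`).
- EDF support is read-only and trusts the file header's sampling rate and
  labels; amplitudes are taken at the file's physical scale.
- The generator's burst waveform (Hann-enveloped band-limited noise) is a
  morphological surrogate adequate for onset detection, not a
  physiological motor-unit model.
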