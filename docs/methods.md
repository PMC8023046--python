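# Methods

This note documents the models, parameter choices and numerical
conventions behind `lungsound`, and what the synthetic-data validation
does and does not establish.

## Signal model and preprocessing

Recordings are mono, normalized to [-1, 1], and resampled to a canonical
8 kHz on load (lung-sound energy lies essentially below 2 kHz; the
canonical rate is an implementation convention, not a device fact).
Time is measured in seconds from recording start and events are
half-open intervals `[onset, onset + duration)`.

Validity screening rejects recordings shorter than `min_duration`
(default 9 s — two full breathing cycles) as `too_short`, and as
`low_quality` those with more than `clip_fraction_max` (default 1%) of
samples at full scale or with RMS below 1e-5 (dead channel). The
screening criteria operationalize a named-but-undefined rejection rule;
both thresholds are exposed.

All detection operates on a zero-phase 4th-order Butterworth band-pass
(default 100–2000 Hz, covering both crackle and wheeze energy at 8 kHz
sampling) with the mean removed. Zero-phase filtering keeps event
onsets unshifted.

## Crackle detection

The defining criteria are a duration below 20 ms and a peak magnitude
more than twice the average magnitude. Two operationalizations needed
care:

* **Envelope.** The detection envelope is a 1 ms *peak-hold* (moving
  maximum) of the rectified signal. A 1 ms moving *average* was tried
  first and rejected: a crackle modelled as a damped sinusoid with
  `tau = duration/5 = 2 ms` loses ~50% of its peak under averaging,
  which pushes genuine transients below any fixed ratio threshold while
  noise excursions remain. Peak-hold preserves the transient's peak
  exactly and, combined with the 2 ms run-closing gap
  (`crackle_merge_gap`), keeps a low-carrier-frequency crackle from
  splitting into sub-runs at its zero crossings.
* **Magnitude reference.** "Average magnitude" is implemented as the
  running mean (sliding 1 s window) of the 20 ms short-time peak
  magnitude. For a Gaussian-like background the mean *absolute*
  amplitude is ≈ 0.8σ, and the signal's own envelope crosses twice that
  level hundreds of times per 9 s recording — a 2× threshold referenced
  to mean absolute amplitude is not selective on any realistic noise
  floor. The mean of short-time *peaks* sits near 2–2.5σ, so twice that
  (~4–5σ) is crossed only by genuine outlier transients; measured false
  crackle events on normal simulated recordings are ≈ 0 per recording.
  The sliding window makes the reference follow the breath-cycle
  amplitude modulation, which a global reference cannot
  (`reference="global"` is available but fires on breath-envelope peaks
  under deep modulation). Both thresholds are pure ratios, so detection
  is invariant under positive amplitude scaling.

Runs above threshold shorter than `crackle_max_duration` (20 ms) become
events; longer bursts fail the crackle criterion by definition. The
detector's sensitivity floor is a peak ratio of roughly 6–7× the mean
background magnitude (i.e. ≈ 4–5× background RMS): below that, a
transient is within the range of the background's own 9 s extreme
values and cannot be separated by an amplitude criterion at any useful
false-alarm rate. At the default 20 dB operating point (peak = 10×
background RMS) event recall is ≈ 1.0.

## Wheeze detection

The rectified band-passed signal is smoothed with a normalized 200 ms
Hamming-window moving average; a sample is wheeze-active when the
maximum of that envelope within the 160 ms window centred on it exceeds
`wheeze_margin` (default 2.0) times the envelope's global mean. A bare
mean-crossing fires continuously on noise, so the margin parallels the
crackle criterion's factor of two. Active runs separated by less than
`merge_gap` (50 ms) merge before the duration test; runs of at least
`wheeze_min_duration` (500 ms) are reported. The 160 ms maximum filter
widens each run by ~80 ms per side, which the duration examples in the
test suite account for.

## Synthetic recordings

The simulator generates what the detector assumes, with exact event
logs:

* **Background**: pink-weighted (1/f power) Gaussian noise band-passed
  to 100–1000 Hz, the classic band of normal vesicular breath sounds,
  amplitude-modulated by a raised-sinusoid breath envelope with period
  3 s and a relative floor of 0.4 — breathing is audible in both
  respiratory phases, and a non-zero floor avoids the unrealistic
  silence a full-depth raised cosine would produce at the trough.
* **Crackles**: unit-peak damped sinusoids `exp(-t/tau) sin(2π f t)`,
  `tau = duration/5`, carrier uniform in 200–2000 Hz, duration 10 ms by
  default (< 20 ms always), scaled to `10^(snr_db/20)` times the local
  background RMS at the onset (floored at the global RMS). Local
  scaling reflects the flow dependence of real crackles — they ride the
  breath cycle — and keeps the logged peak ratio at or above the
  requested value.
* **Wheezes**: monophonic tones with 50 ms raised-cosine ramps
  (polyphonic wheezes are out of scope), 0.8–2.0 s long at 200–800 Hz
  in corpora.
* One event kind per recording; mixed crackle+wheeze recordings are
  excluded from study corpora by construction and the simulator raises
  on such a request.

The default corpus operating point is `snr_db = 20` (event peak 10×
background RMS): gold-standard-grade adventitious sounds — ones three
specialists agree on — are prominent, clearly audible events, and 20 dB
is the reference level used throughout the classification examples.
At `snr_db = 10` a crackle's peak (≈ 3.2× background RMS) falls below
the background's own 9 s extreme values (≈ 3.8σ), so event-level
crackle recall necessarily collapses there; the classification accuracy
sweep over 20/10/0 dB shows the corresponding graceful degradation at
recording level, where features integrate over the whole signal.

What the simulator does **not** model: heart sounds, crying/speech
interference (a tone-burst contaminant generator exists but is off by
default), transmission effects of the chest wall, polyphonic or
biphasic wheezes, and respiratory-phase structure beyond amplitude
modulation. Passing tests on this corpus therefore demonstrate
correctness of the rules and pipeline plumbing, not clinical
performance on real recordings.

## Features and classifier

Features are computed on the band-passed full recording (the classifier
operates at recording granularity, matching per-recording labels): a
full wavelet-packet tree, orthogonal wavelet `db6`, depth 4 → 16
uniform 250 Hz subbands in natural frequency order; per node the
log-energy `log(max(Σc², 1e-12))` and the normalized Shannon entropy of
the squared coefficients. db6/depth-4 is the common choice in the
lung-sound wavelet literature; both are parameters. The zero-extension
signal mode makes the transform exactly energy-conserving (Parseval is
asserted to 1e-8 relative in the tests). Log-energies shift by
`2 log c` under amplitude scaling by `c`; entropies are
scale-invariant.

The classifier is a one-vs-rest RBF SVM (`C = 1`,
`gamma = 1/n_features`) on features standardized by the training
mean/variance, with inverse-frequency class weights for imbalanced
corpora. Kernel and regularization are implementation defaults, exposed
as hyperparameters. The model bundle stores the feature-name contract,
class order, seed, hyperparameters and an order-independent SHA-256
fingerprint of the training labels; prediction refuses feature vectors
whose names mismatch, and loading refuses foreign or truncated files
and version mismatches. An optional hybrid mode appends the rule-based
detector's event counts as two extra features (off by default, keeping
the default contract purely spectral).

## Consensus rules

"Unable to distinguish" is modelled as an explicit `indeterminate`
rater label. The decision function is total over the 4³ = 64 possible
triples and symmetric under rater permutation; exhaustive enumeration
partitions the space into 3 unanimous-accept, 34 reject and 27
needs-adjudication triples, verified against an independent in-test
oracle. The `(X, X, indeterminate)` triple is referred to the experts
rather than accepted — only fully consistent triples qualify directly —
with a policy switch (`accept_majority_with_indeterminate`) for the
alternative reading. Adjudication of a non-pending decision is a state
error.

## Metrics and numerical conventions

All per-class metrics derive from the 3×3 confusion matrix by
one-vs-rest reduction; the macro "mean" row averages the two
adventitious classes only (crackle and wheeze), matching how such
summaries are conventionally tabulated. Undefined values
(zero denominators) propagate as `None`, never as silent zeros.
Internal computation is full precision; `round1` applies half-up
one-decimal rounding at the reporting layer only, operating on the
float's shortest decimal representation so that values like
`(94.1 + 83.0)/2` round as the decimal 88.55.

Cohen's kappa (unweighted default — the labels are nominal — with
linear/quadratic weighting options over an explicit category order) and
its asymptotic 95% CI (`kappa ± 1.96·SE`) are delegated to statsmodels
behind the module surface and cross-checked against a direct po/pe
oracle in the tests. Kendall's W uses mid-ranks with the standard tie
correction `W = 12S / (m²(n³−n) − mT)`; nominal labels require an
ordinal embedding whose default order (normal < crackle < wheeze) is
arbitrary, configurable, and stated here because W's value depends on
it. The chi-square test is the Pearson statistic without continuity
correction.

## Problem sizes

The test suite and acceptance script use corpora of 30 recordings
(10 per class) for cross-validation studies, 5 seeds per
signal-to-noise level for the degradation sweep, and a 201-recording
corpus for detector rule-fidelity and recall measurement — sizes at
which every reported quantity is stable to well within its assertion
margin while the whole suite stays fast.

## Known limitations

* The detector cannot beat the amplitude-criterion information limit:
  crackles below ≈ 4× background RMS are undetectable at a useful
  false-alarm rate, and no windowing choice changes that.
* The wheeze detector is monophonic and reports no pitch; overlapping
  wheezes merge into one event.
* The classifier is validated on synthetic data only; its clinical
  performance is untested by construction.
* Recordings are assumed free of heart-sound and vocal interference;
  the contaminant generator exists for robustness experiments only.
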