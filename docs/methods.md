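# Methods

This note documents the models, defaults and numerical choices behind
`mmncoh`, and what the synthetic-data layer does and does not establish.

## Stimulus sequences

**Optimum-1.** Three blocks, each 15 formation standards followed by 600
stimuli on a constant 0.5 s SOA grid, alternating deviant/standard so that
every second non-formation tone is the standard. Per block the 300 deviant
slots hold 60 of each of the five families (duration, gap, frequency,
intensity, location); the family order is drawn by a guarded greedy shuffle
under the constraint that consecutive deviants differ in family (a
feasibility guard places a family whenever it holds more than half of the
remaining slots, which cannot fail for balanced counts). Two-variant
families (frequency ±10%, intensity ±10 dB, location left/right) are split
exactly 50/50 within each block. Totals: 1,845 events; among the 1,800
non-formation tones 50% standards and 10% per deviant family. The published
probabilities exclude the formation tones; this is recorded in the sequence
metadata.

**Memory-Trace.** Three blocks of 154 events: 15 formation standards, then
52 cycles of a 1–3 standard run followed by one deviant (26 duration + 26
frequency per block, randomly ordered). Run lengths start at 1 and receive
35 random unit increments capped at 3, giving 87 non-formation standards per
block. The ISI preceding every deviant is exactly 3 s; all other ISIs are a
shuffled fixed multiset of 34×0.5 s, 34×1.5 s and 33×3 s per block. The
fixed composition realises the "pseudo-random {0.5, 1.5, 3} s" assignment
while *guaranteeing* (not merely in expectation) that each block lasts
≈ 5.6 min and fits its 6-min slot for every seed. Totals: 462 events, 306
standards (66.2%), 78 per deviant type (16.9%) — the formation tones are
included in these totals, which is the only integer composition consistent
with the printed percentages.

**Tones.** The standard is the sum of 500/1000/1500 Hz sinusoids at
0/−3/−6 dB with 5 ms linear rise/fall ramps (the ramp shape is a
convention; nothing downstream depends on it), 75 ms total, rendered at
50 kHz so the 800 µs ITD is exactly 40 samples. The master gain puts the
standard's peak at 0.25 full scale, leaving 10 dB headroom for the loud
intensity deviant. At sampling rates where 800 µs is not an integer number
of samples the location deviants raise an error unless the windowed-sinc
fractional-delay mode is enabled. The gap deviant's 7 ms silence includes
its 1 ms fall/rise edges and is centred in the tone.

## Synthetic EEG

**Resting / coherence ground truth.** Channel c is
`x_c = a_c s + sqrt(1 − a_c²) n_c` with `s`, `n_c` independent unit-variance
Gaussian processes whose spectra are flat on 1–30 Hz and zero outside
(frequency-domain construction; each realisation is rescaled to unit sample
variance so the mixing ratio holds exactly in-sample). For unit-variance
processes the magnitude-squared coherence (MSC) of channels i, j is
`a_i² a_j²` at every in-band frequency; the global index's analytic value is
the mean of that over all pairs (`expected_global_msc`). Band-limited
Gaussian sources were chosen over AR processes precisely because this closed
form is exact and flat across the band; an optional 1/f ("pink") mode exists
without a closed form. Default: 120 s at 200 Hz, 10 µV RMS.

**Oddball epochs.** Standards are white Gaussian noise (trial SD 10 µV by
default); deviants add `A·exp(−(t − µ)²/2σ²)` (defaults A = −2 µV, µ =
150 ms, σ = 30 ms) on the fronto-central target channels. Mastoids never
receive the component, so the linked-mastoid reference leaves the injected
amplitude intact while adding mastoid noise to every channel — the recovery
tests account for that variance. The topography is a flat unit weight on the
target set, not a dipolar field: sufficient because the analysis only reads
the Fz/FCz/Cz cluster against the mastoids.

**Cohort.** Subjects (defaults 16 CT / 18 PT / 20 WLC, the scale of a small
three-arm trial) have lifestyle `L ~ Beta(5.7, 13.9)` (mean 0.29, SD 0.10 —
the scale of a CHAMPS variety index in senior cohorts), baseline outcome
0.30 ± 0.10 between subjects (a global-coherence-like scale), residual SD
0.09 per observation, and a pre→post change of
`retest + β_group + β_lifestyle·L` plus noise. All defaults are null
(β = 0); tests switch effects on explicitly.

## Preprocessing

Both branches use a zero-phase 4th-order Butterworth band-pass
(24 dB/octave magnitude rolloff, applied forward–backward with
`sosfiltfilt`): 1–30 Hz for coherence, 1–35 Hz for MMN. Bad channels are
flagged deterministically — variance below 0.01 µV² (flatline) or a robust
z-score (median/MAD) of channel variance above 5 — as an automated proxy for
manual screening; the proxy is documented, not claimed equivalent. For
longitudinal coherence comparisons both assessments of a pair are analysed
on the matched channel set (montage minus the union of the two bad sets).
Interpolation uses the average method: mean of good spatial neighbours, with
a global good-channel mean fallback.

Resting epochs are a contiguous 2 s grid — 0.5 Hz spectral resolution and
59 bins in 1–30 Hz; stimulus-locked epochs are −100…+500 ms with
−100…0 ms baseline subtraction (both conventional; the source protocol does
not state them). Artifact proxy: drop any epoch exceeding 100 µV absolute or
150 µV peak-to-peak on a good channel (configurable). Trial subsampling is
uniform without replacement, order-preserving, seeded per
subject/session/stage via SHA-256 of the global seed (always below 2³¹).

## Coherence estimation

MSC per pair and bin with auto-/cross-spectra averaged across trial epochs,
one Hann taper per epoch and no sub-windowing — with the 20-trial protocol
each trial is one averaging segment. The estimator is checked against a
brute-force DFT implementation to 1e-10 on small instances. Two known
properties matter for interpretation:

* **Bias.** `E[ĉ] ≈ c + (1 − c)²/L` for L averaged trials; independent
  channels give ≈ 1/L, not 0. This is why the trial count is fixed across
  subjects and assessments.
* **Reference interaction.** A common-average reference removes a spatially
  *uniform* shared source entirely, so the closed-form ground truth applies
  to unreferenced data; recovery validations bypass the reference step, and
  the pipeline summary reports both referenced and unreferenced values.

Magnitude-squared coherence is the default (the common convention of
spectral connectivity toolboxes); an unsquared-magnitude mode is available
by flag since published "spectral coherence" values are ambiguous between
the two. Spectra are estimated nonparametrically; autoregressive spectral
estimation (used by some older toolboxes) was deliberately not reproduced —
the oracle test pins down what this estimator computes. Band endpoints are
inclusive.

## MMN measurement

Mean amplitude (not peak) of the deviant-minus-standard difference wave,
averaged over Fz/FCz/Cz, in a 100–250 ms post-onset window — a standard MMN
quantification; window and cluster are arguments, never hidden. The window
is onset-locked; the duration deviant's physical point of deviance (25 ms)
does not shift it. Formation tones are excluded from the standard average by
construction (they carry their own label upstream). ΔMMN = MMN(short ISI) −
MMN(long ISI), duration deviant only; a missing input raises — subjects
without both paradigms are excluded, never imputed. The analytic expectation
of a measured amplitude is the Gaussian's window mean (erf closed form),
`A × 0.477` for the default window and component.

## Lifestyle index

Activities are assigned to every domain (cognitive/physical/social) whose
mean rater score strictly exceeds 3 on the 1–5 demand scale; the mean across
raters is the aggregation (the natural reading of a panel rating), and
adjudicated reassignments are supported as explicit overrides. The index is
the mean over the three domains of the fraction of the domain's activities a
subject reports in a 4-week span; multi-domain activities count in each
domain. Performed yes/no only — no frequency or energy weighting. Rater
consistency uses Cronbach's α with raters as items across activities
(sample variances throughout, so the k = 2 Spearman–Brown identity
`α = 2r/(1 + r)` holds exactly on standardized scores).

## Statistical layer

`outcome ~ group*time + lifestyle*time` with a subject random intercept,
WLC and pre as reference levels, fitted via `statsmodels` MixedLM. REML is
the default (matching the defaults of the mixed-model software family these
trial analyses traditionally use); `reml=False` is available, and the choice
is recorded in the result. Interaction tests are Wald F pooling the term's
contrasts (2 numerator df for Group × Time with pre/post, 1 for
Lifestyle × Time) with containment-style denominator df:
`n_obs − n_subjects − (fixed-effect columns varying within subject)`. A
degenerate fit (e.g. zero residual variance) falls back to OLS for the fixed
effects — valid for balanced designs, where mixed and OLS fixed-effect
estimates coincide — and is flagged `singular`, never silent. Missing
sessions are handled by likelihood, not listwise deletion. Null simulations
at group sizes 16/18/20 put both tests' type-I error near 0.04–0.05.

A reduced Group × Time-only model (`include_lifestyle=False`) mirrors
analyses where no lifestyle association is hypothesised. Baseline
z-standardization uses the pre-session mean and SD of the full sample for
both sessions; change CIs are t-based on post − pre. Component scores are
weighted averages of z-scored variables with |loading| ≥ 0.40, weights
renormalized to unit absolute sum (the normalization rule is a package
choice; "weighted average" alone underdetermines it), with a sign map for
direction-coded variables. Hedges' g uses the exact small-sample correction
J and a normal-approximation CI (the method behind published g CIs is
typically unstated; the choice is recorded in the output).

## Problem sizes

The validation suite uses: 420 s of simulated resting EEG at 200 Hz with
200 trials for coherence recovery at five mixing weights; 100 simulated
subjects (120 standard + 60 deviant trials each, 500 Hz) for ΔMMN recovery
under the 50-trial protocol; 1,000 null cohorts for type-I calibration.
These sizes put Monte-Carlo error well below the assertion tolerances
(3 SE for coherence, 0.15 µV for ΔMMN, ±0.02 around the nominal 0.05
rejection rate).

## Limitations

* Synthetic EEG has no biophysical forward model, no ocular/EMG artifact
  morphology (artifacts are amplitude outliers only), and flat in-band
  spectra; passing recovery tests demonstrates correctness of the analysis
  chain on its generative assumptions, not robustness to real-data
  pathologies such as non-stationarity, volume conduction gradients, or
  structured artifacts.
* The bad-channel and artifact thresholds are proxies for manual expert
  screening and were not tuned to reproduce any human rater.
* EDF export is not provided (recordings round-trip through the native
  npz + JSON format); EDF reading requires the optional `mne` dependency.
* Published cohort-level results from real trials are not reproducible from
  this package by construction — the package reproduces protocols and
  estimators, not unavailable raw data.
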