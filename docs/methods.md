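# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `dyadvox`, in the order the pipeline runs.

## Corpus model

A corpus is couples x timepoints (`pre`, `26wk`, `2yr`) x topics
(husband-chosen, wife-chosen issue), each cell one two-speaker
interaction.  One *outcome sample* pairs the two pre-therapy
interactions with the two at a follow-up horizon and carries a rating
in {1 deteriorated, 2 no change, 3 improved, 4 recovered}.  A couple
contributes at most two samples (one per horizon), and both share the
identical pre-therapy data by reference.  Couples missing one of the
two topic interactions at either timepoint are excluded at assembly,
because the fixed-dimension feature vectors require all four
interactions.

The reference class mix used for chance-rate computations is
12/26/34/67 across ratings 1–4 (139 samples).  Published descriptions
of comparable corpora sometimes quote 141 outcome instances alongside
these per-class counts; the counts and the chance rates they imply
(51.8 / 47.2 / 48.2%) are internally consistent at 139, so this
package uses the counts.

Times are session-relative seconds, intervals half-open [start, end).
Segments and turns use an RTTM dialect (onset/duration in seconds, 3
decimals); audio is 16 kHz 16-bit PCM WAV; tables are UTF-8 CSV.

## Pre-processing

**VAD.** A frame (25 ms window / 10 ms hop) is speech when its energy
clears an adaptive threshold — the 10th-percentile noise floor plus a
10 dB margin, never below −55 dB — and its spectral flatness
(geometric over arithmetic mean of the power spectrum) is below 0.5.
Runs are merged across gaps < 0.2 s and dropped below 0.2 s.  This is
a deliberately simple detector with the same interface a trained
classifier would have; on clean synthetic renderings it recovers
segment boundaries to within one window.

**Speaker-change detection.** Within each speech region, two adjacent
1.0 s windows slide at 0.1 s steps over the 15 MFCC columns; the GLR
statistic is `L(merged) − L(a) − L(b)` with `L = (n/2)·logdet` of the
ML full covariance (regularized by 1e-6·I).  Local maxima above a
threshold of 110 are change candidates.  The threshold was frozen once
from a stationary-Gaussian null calibration (95th percentile of the
per-track maximum over 10 s tracks), giving a ≤5% per-track false-alarm
rate; a 5-SD mean shift scores ~5x the threshold.

**Clustering and roles.** Speaker-homogeneous pieces are merged
greedily by smallest pairwise GLR (pooling frames after each merge,
ties to the earliest segment) down to two clusters.  The cluster with
the higher mean voiced pitch is the wife; equal means tie-break to the
earlier cluster as husband, with a warning.  Turns are same-role
segments merged across gaps < 0.3 s, discarded below 0.2 s — the
operational definition of "turn" used throughout.

**DER** is (missed + false-alarm + confusion time) / reference speech
time on a 1 ms grid, minimized over the two role mappings.

## Frame-level features (74)

37 base descriptors and their deltas: 15 MFCCs (c1–c15 of a 26-filter
unit-area mel bank; c0 is excluded as redundant with intensity), 8 log
mel-band energies (separate 8-band bank), 8 line spectral frequencies
(order-8 autocorrelation LPC; degenerate frames fall back to the
uniform grid), intensity (dB), pitch, loudness, jitter, shimmer, HNR.

* **Pitch**: per-frame normalized autocorrelation over a 40 ms window,
  search range 75–500 Hz, with the unbiased-lag correction
  (r(τ)/(1−τ/N)) and a 0.05-per-octave cost discouraging halving
  errors; parabolic peak interpolation.  Voiced = peak correlation
  > 0.45 and energy > −60 dB.  Accuracy on synthetic harmonic signals
  is better than 1% over 90–400 Hz.
* **Loudness**: Σ_b E_b^0.3 over the 26 mel bands — a standard
  perceptual compression.
* **Jitter/shimmer**: relative mean absolute difference of consecutive
  cycle periods / peak amplitudes, cycles found by sub-sample-refined
  peak picking in a ±3-period window around each voiced frame.
* **HNR**: 10·log10(r/(1−r)) of the corrected autocorrelation peak,
  clipped to [−20, 60] dB.
* **Deltas**: 5-point local regression slope per frame.  Missing
  values (pitch and voice quality on unvoiced frames) propagate: the
  fit uses only finite neighbours, a frame whose own value is missing
  gets a missing delta, and windows shrink at run edges.  Zero-filling
  is deliberately forbidden — it would bias both deltas and
  functionals.

## Functionals

The statistic set is {mean, median, SD, min, max, IQR} — six per
series.  Six is forced by the bookkeeping identity
3552 = 74 features x 6 statistics x 8 (speaker, topic, timepoint)
slots; this particular six is the minimal standard choice and is
configurable.  SD uses the population convention (a single observation
has SD 0, logged).

* **Static**: the 6 statistics per feature per speaker per interaction.
* **Short-term**: per-turn feature means (turns with < 3 frames are
  dropped), then adjacent-turn differences HH, WW (within speaker,
  skipping the other speaker's intervening turns) and HW (wife turn
  minus the immediately preceding husband turn).  WH is omitted as the
  sign-reversed HW sequence.  The 6 statistics apply to each delta
  sequence per feature per interaction: 74 x 6 x 3 x 4 = 5328 values.
* **Long-term**: per interaction, silence is removed, each feature is
  z-normalized over the session (both spouses' speech frames pooled;
  zero-SD features map to 0, preventing infinities), the pooled frames
  are split into four equal-count quarters, and per-quarter per-spouse
  means of the post session minus the pre session are taken:
  74 x 4 quarters x 2 spouses x 2 topics = 1184 values.  The
  construction is antisymmetric under pre/post exchange and invariant
  to per-session affine re-scaling of any feature (recording-condition
  mismatch), both property-tested.

Dynamic = short-term + long-term = 6512 under these defaults;
`acoustic_all` = static + dynamic; `all` adds the 264 code features.
Published table layouts for comparable analyses quote a dynamic
dimension of 6696 and an all-features dimension of 9144, which are not
decomposable from the stated construction; this package documents its
own bookkeeping rather than forcing those totals.

Vector order is canonical — timepoint-major, then topic, speaker,
feature, statistic — and written to a sidecar registry so vectors are
byte-comparable across runs.

## Behavioral codes

33 codes (20 SSIRS + 13 CIRS) per spouse per interaction, 1–9 scale;
the annotator mean is the reference, giving 33 x 2 x 2 x 2 = 264
features per sample (the per-interaction reading is the only one
consistent with that dimension).  Agreement is interval-metric
Krippendorff α, missing-tolerant, offered both pooled over all
(interaction, spouse, code) units and averaged per code — which of the
two a published aggregate used is typically unstated, so both are
provided.

## Selection and classification

Outcome binarization for correlation analysis: rating 4 → 1, else 0.
Pearson r with the two-tailed t-transform p-value (n−2 df);
zero-variance features are skipped with a log entry.

MIM scores each feature by plug-in mutual information (bits) with the
class label after equal-frequency discretization into 10 bins; NaNs
get a dedicated bin, constant columns score 0.  The estimator is a
documented stand-in for toolbox-specific discretizations that are
rarely reported.  Selection keeps the top k, ties to the lower
canonical index; k is chosen per training fold from
{5, 10, 15, 20, 25}% of the dimension by inner cross-validation at the
reference operating point (C=1000, γ=0.001), after which the full
(C, γ) grid search runs on the selected set.  The default grid is
C ∈ {1, 10, 100, 1000, 10000} x γ ∈ {1e-4 … 1}, which contains that
reference optimum.

The classifier is a one-against-all RBF SVM (one binary machine per
class, margin argmax, ties to the lowest rating).  Outer CV is 10-fold
with couples dealt round-robin after a seeded shuffle, both samples of
a couple in one fold, re-drawn (bounded) until every class appears in
every training split.  Median imputation, z-normalization, MIM
selection and the grid search are all fit on the training split of the
fold at hand — stricter than any plausible alternative reading, chosen
to preclude leakage — and each fold records the sample ids its fitted
statistics touched, which the tests assert are disjoint from the test
split.  Class imbalance is deliberately left unhandled so chance-rate
baselines stay comparable.

## Evaluation

Per-fold accuracy and macro-averaged F1 (macro chosen for imbalance
sensitivity), summarized as mean and population SD across folds;
percentages print to 1 decimal, F-scores to 2.  Chance is the
majority-class rate on the experiment's domain.  Two feature sets are
compared by an exact McNemar construction: among pooled out-of-fold
predictions where exactly one system is correct, the count favoring A
is tested against Binomial(n, ½), two-tailed; the trial definition for
published binomial comparisons of this kind is usually unstated, and
this is the standard paired-classifier choice, stated prominently for
auditability.  The accompanying 95% Clopper–Pearson interval is for
the proportion of discordant samples favoring A — one plausible
reading of "the statistic", flagged as such.  Zero discordance yields
p = 1 with a degenerate interval, logged.

## Synthetic corpus generator

The generator emulates the study conditions: a 12/26/34/67 outcome
mix (sampled per couple), 88 couples by default with both horizons
present with probability 53/88, two topics per timepoint, alternating
H/W turns (20–30 per interaction, 1–3 s each, 0.2–0.8 s gaps), base f0
110 Hz (H) / 210 Hz (W).  Turn-level feature deviations follow an
AR(1) (coefficient 0.6) within speaker plus a 0.3 cross-speaker
coupling term, so short-term deltas and the HW entrainment channel are
non-trivial; frame values add white noise around turn means on the
10 ms grid, and delta columns are computed through the same regression
code the real front-end uses.

Class effects are graded by (rating − 2.5)/1.5 and scaled by
`effect_size` (default 1): recovering couples get a rising within-turn
pitch contour (+15 Hz/s per unit effect, driving the mean pitch-delta
functional positive), inflated turn-to-turn loudness variability
(+50% SD per unit, driving the loudness-SD functional), lower jitter
(−0.003 per unit), positive post-session shifts in loudness and
intensity (making long-term quarter deltas informative), and
behavioral-code ratings shifted 0.8 per unit toward each code's pole
(positive codes up, negative codes down).  Ratings add a per-cell
latent spread (SD 2.0) shared across annotators and annotator noise
(SD 1.2), which yields interval-α ≈ 0.73 — in the range reported for
trained coding teams.  The effect *directions* mirror the strongest
associations this kind of analysis reports (loudness variability and
pitch change positive, jitter negative); the magnitudes are free
generator parameters, not empirical claims.  With `effect_size = 0`
every channel is exchangeable across classes, which the null
calibration tests exploit.

Audio rendering is deliberately schematic: each turn is a band-limited
sawtooth-like harmonic complex at the role's f0 with slow vibrato and
an attack/decay envelope, with silent gaps.  It exercises VAD, GLR
segmentation, clustering, role assignment and pitch tracking with
exact ground truth; it does not contain formants, consonants, prosodic
phrasing, channel noise or overlapped speech.  Passing tests therefore
demonstrate the correctness of the machinery and the recoverability of
injected structure — not field performance on real recordings, where
diarization error (reported near 28% on far-field clinical audio) is
the binding constraint.

## Problem sizes in tests and the acceptance script

Multi-seed suites (null calibration, sign recovery across 50 seeds)
run the generator at reduced interaction sizes — 6–12 turns of
0.4–1.0 s — and the cross-validation runs use reduced search grids
(C ∈ {10, 1000, 10000}, γ ∈ {1e-3, 1e-2, 1e-1}, k ∈ {5, 10}%, 3 inner
folds).  These are problem-size choices for the simulation studies;
the defaults documented above remain the package defaults.  The
acceptance script's Experiment-1 run uses 120 couples (~200 samples,
3552-dim static vectors) at those scaled sizes.

## Known limitations

* The 74-feature inventory is a reconstruction: published descriptions
  of this design enumerate categories (spectral, prosodic, voice
  quality, each with derivatives) rather than the exact list; the
  decomposition 31 spectral + 3 prosodic + 3 voice-quality, doubled by
  deltas, is the unique natural reading consistent with the stated
  total and the reported loudness functional.
* The VAD is an energy/flatness detector, not a trained classifier;
  the GLR threshold is calibrated on synthetic nulls, not on speech.
* No overlapped-speech handling; exactly two speakers assumed.
* Whether short-term functionals should be pooled across topics or
  computed per topic (this package: per topic, per timepoint) is an
  open reading; the choice is recorded in the feature-name registry.
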