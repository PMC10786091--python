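# Methods

This note documents the models, parameters and numerical choices behind
`animrsa`, and what the synthetic validation does and does not establish.

## Stimulus design model

Twelve classifiers (3 each: human, animal, natural-object, artifact) are
paired with 10 congruent nouns each (nouns drawn from the classifier's own
subgroup).  Incongruent phrases re-pair every noun exactly once:
within-animacy re-pairings (human ↔ animal, natural-object ↔ artifact)
yield the *incongruent, animacy-match* condition; cross-animacy
re-pairings (human ↔ natural-object, animal ↔ artifact) yield *incongruent,
animacy-mismatch*.  The result is 240 distinct classifier–noun pairs:
120 congruent, 60 match, 60 mismatch.  Which particular noun goes to which
classifier within a subgroup is not determined by the counts; we draw it
uniformly at random under the seed, subject to each noun being reused
exactly once.  Blocking splits trials into three blocks of 80 (40
congruent / 40 incongruent, stratified by the three-level condition when
divisible) and randomizes order within block.  Scaled-down designs (for
tests) are supported for the four-subgroup scheme and for a two-subgroup
scheme with opposite animacy, where all incongruent trials are mismatches.

Lexical norms (stroke counts, log frequencies) are synthetic, drawn from
identical distributions in every subgroup (uniform 4–14 strokes; normal
log frequency 1.5 ± 0.4) so that groups are matched in expectation, which
is what the matching tests verify on real stimuli.

## Synthetic EEG generator

Epochs span −2,500…+1,000 ms around noun onset at 500 Hz (1,750 samples =
3,500 ms: 500 ms pre-stimulus, 1,000 ms classifier, 1,000 ms blank,
1,000 ms noun), 62 channels with 10-10 labels.  Per-trial signal, in μV:

* **Pre-activation pattern** — `pred_amplitude` (5 μV) × Hann envelope on
  `pred_window` (−240–0 ms) × the trial noun's spatial pattern.  Noun
  patterns implement the ground-truth similarity structure:
  `sqrt(rho_g)·shared_g + sqrt(1−rho_g)·unique`, all components i.i.d.
  standard normal over channels, so the expected pairwise within-group
  correlation is `rho_g` (defaults ρ_animate = 0.5, ρ_inanimate = 0.1).
* **Prediction potential** — a deterministic negative shift,
  `pred_shift` (2 μV) × the same envelope × a fixed centro-parietal
  topography peaking at Cz, giving the slow pre-noun negativity that the
  one-sample fronto-central test detects.
* **N400** — a negative deflection, weight × `n400_amplitude` (3 μV) ×
  Hann envelope on 300–500 ms × the centro-parietal topography.  Weights:
  congruent 0; incongruent-match 1; incongruent-mismatch 2 under
  animate-constraining classifiers but 1 under inanimate-constraining
  ones, so the *extra* animacy-mismatch negativity exists only on the
  animate side — the asymmetry the ROI contrasts must recover and the
  inanimate null they must not invent.
* **Noun perception** — `noun_amplitude` (2 μV) × Hann envelope over the
  noun display (0–1,000 ms) × the noun pattern.  This carries the
  within-group similarity structure into the after-noun window, where the
  noun-locked RSA (items = each classifier's ten congruent nouns) finds
  greater animate similarity throughout noun presentation.  It also adds
  item-driven across-subject variance to the N400 cell means — a
  realistic consequence of item sampling that makes the mismatch
  contrasts noticeably harder at small n than pure sensor noise would.
* **Noise** — i.i.d. Gaussian per channel and sample, `noise_sd` = 14 μV;
  optionally AR(1) along time (`ar_coef`) with the same marginal sd.
  14 μV was chosen so that the ±70 μV criterion rejects roughly 5% of
  trials at full scale, the regime the pipeline is meant to operate in.
  An optional per-classifier evoked pattern during the classifier display
  (`classifier_amplitude`, default 0) can add item-specific but
  group-unstructured activity; with the default off, the pre-noun
  closed-form identities hold exactly at `noise_sd = 0`.

Item patterns are drawn per subject by the pipeline drivers
(subject-specific representational geometry), which gives the
condition contrast realistic across-subject variance; a single shared
pattern set may be passed instead.

Behavior: responses exist only for incongruent trials (the task is to
reject implausible phrases).  RT = 674 − 22·1[mismatch] + N(0, 195) ms,
floored at 100 ms; accuracy is Bernoulli(0.953).  These constants are the
printed condition means, overall SD, and error rate of the behavioral
data the generator emulates.

## Preprocessing

Filtering is a zero-phase Butterworth band-pass (order 4, `sosfiltfilt`),
with reflection padding extended to cover the filter's impulse response.
A caveat documented here because it bit during development: a 0.1 Hz
high-pass belongs on *continuous* recordings; applied to 3.5 s epoched
segments its edge transients (time constant of seconds) leak into
epoch-initial baseline windows and can shift whole epochs past the
rejection threshold.  On epoched synthetic data use a ≥0.5 Hz high-pass,
or skip filtering — the synthetic signal is band-limited and the noise
white, so the pipeline drivers default to no filter.

Baseline correction subtracts the per-trial, per-channel mean over a
half-open window `[start, end)` — the window convention everywhere in the
package, inclusive of the sample at `start`.  The epoch-level baseline is
the 500 ms pre-classifier interval; the prediction-potential analysis
re-baselines on (−300, −200) ms before measuring (−200, 0) ms, both
overridable.  Rejection drops trials whose |amplitude| strictly exceeds
the threshold (70 μV default) on any channel/sample, plus incongruent
trials answered incorrectly, and raises a degenerate-data error if any
subject loses every trial of some classifier.  Rejection is evaluated
after filtering and baselining, since thresholding raw drifting data
would reject trials the high-pass rescues.

## RSA and cluster inference

The spatial vector is channels-only (62 values per time point).  Pairwise
Pearson r values are averaged raw by default; Fisher-z averaging is a
flag.  Pairs whose spatial vector is constant at some time point are
undefined there and excluded from that time point's mean (counted in
`n_valid`); an all-constant time point raises a degenerate-data error.

The condition contrast is a paired t across subjects per time point
(df = n−1).  Time points with zero variance are NaN (degenerate) unless
the difference is identically zero (t = 0); NaNs are sub-threshold for
cluster forming.  Candidate clusters are maximal contiguous *same-sign*
runs with two-sided p < .05 — a sign flip starts a new cluster so cluster
mass never self-cancels, matching reference implementations.

Permutation inference flips the sign of each subject's difference
timecourse (the exact consequence of swapping two within-subject
condition labels).  Two variants:

* `max_cluster` (default): every permutation re-thresholds and re-clusters
  its own t series and contributes its maximum |Σt| (0 if none) to the
  null; each observed cluster is referred to that distribution.  This
  controls the family-wise error at the cluster-forming level, and the
  null calibration test holds the empirical significant-cluster rate at
  the nominal 5% over replicate null experiments.
* `fixed_window`: permutations sum t inside the observed window only.
  This narrower recipe is anticonservative — the window was selected for
  extremity, so under the null nearly every selected window beats its own
  within-window null — and is provided for comparison, not inference.

p-values use the add-one rule (1 + #{null ≥ obs})/(n_perm + 1), with a
relative 1e−9 tolerance on the comparison so the identity permutation
ties with the observed value despite round-off differing between the two
computation paths.  Multiple candidate windows are each reported with
their own p against the common max-cluster null.

The pre-noun analysis averages all surviving trials per classifier and
correlates classifier-locked patterns from classifier onset (−2,000 ms)
to noun onset; the after-noun analysis averages each classifier's ten
congruent-noun trials over the noun display (0–1,000 ms).  Whether epochs
are baselined before RSA is the caller's choice; the drivers baseline on
the pre-classifier interval, which leaves the similarity measure
untouched up to a per-channel constant (Pearson r is offset- and
scale-invariant only for *common* transformations, so baselining uses a
window where no condition-specific signal lives).

## ERP battery

Mean amplitude is the average over `[start, end)` samples, listed
electrodes, and surviving trials per subject × condition cell.  The N400
analysis uses nine ROIs (left/middle/right × anterior/middle/posterior)
and a 2 × 3 × 9 within-subject ANOVA (statsmodels `AnovaRM`; no
sphericity correction, matching common reporting practice —
Greenhouse–Geisser is out of scope).  Follow-up contrasts
(incongruent-vs-congruent per ROI; mismatch-vs-match per classifier type
and ROI) are paired t-tests, Benjamini–Hochberg corrected across the nine
ROIs within each family.  The RT contrast compares per-subject condition
means with a paired t by default; the item-level mixed-effects model used
in confirmatory analyses of real data is a routine external fit and is
not re-implemented.

## Taxonomy similarity

Wu–Palmer similarity 2·depth(LCS)/(depth(a)+depth(b)) uses the original
counting convention with the root at depth 1 (the value depends on this
choice, so it is fixed and tested).  The packaged toy taxonomy is
generated programmatically: an extra shared "creature" level under the
animate branch gives animate concepts denser shared ancestry
(within-subgroup pairs 0.8 vs 0.75; cross-subgroup 0.6 vs 0.5), so mean
within-animate similarity (0.68) exceeds within-inanimate (0.60) — the
structural premise of the whole analysis.  It is a stand-in for a
lexical-semantic database, not a reconstruction of one; group tests on it
are structural checks, not value reproductions.  Group comparisons use
Welch's t on within-group pairwise values; pairwise values are not
independent observations, so these p-values are descriptive, as in
standard stimulus-norming practice.

## Validation scales and what passing shows

The recovery test runs 20 experiments at study scale (25 subjects, 62
channels, 500 Hz, 240 trials, ρ 0.5 vs 0.1) and requires a significant
cluster overlapping −240–0 ms in ≥80% of runs with no classifier-interval
cluster in ≥90%.  The null calibration runs 200 replicate experiments at
a reduced scale chosen for throughput (12 subjects, 20 channels, 100 Hz)
— calibration of the permutation test does not depend on those sizes —
and requires the significant-cluster rate to sit inside the binomial 95%
band around 0.05.  The ERP recovery runs one full-scale experiment under
a fixed seed.

Passing these establishes that the pipeline recovers effects it was
designed to detect under its own generative model: Gaussian noise,
stationary patterns, fixed component latencies, no artifacts beyond
amplitude outliers, no volume-conduction structure.  Real EEG violates
all of these to some degree, so the tests certify the *statistics*, not
real-data effect sizes; in particular the true magnitude of the
similarity difference is unknown and is treated as a free parameter
throughout.

## Known limitations

* No forward head model; channel covariance of the noise is diagonal
  (optional AR(1) in time only).
* Component families beyond the injected prediction potential, N400 and
  noun response are absent; no ocular or muscle artifacts, so artifact
  rejection is exercised only by amplitude outliers.
* The per-classifier similarity average ignores that classifier pairs
  share re-paired nouns (a small positive dependence between pairs),
  just as the analysis it implements does.
* Epoch-wise filtering at very low cutoffs is unreliable (see
  Preprocessing); continuous-data filtering is out of scope because the
  generator produces epochs directly.
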