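# Methods

This note documents the models, parameter choices and numerical conventions
behind `osahrv`, and states what the synthetic-data experiments do and do
not demonstrate about real overnight recordings.

## Problem setting

Obstructive sleep apnea (OSA) severity is graded by the apnea-hypopnea
index (AHI, events/h): normal < 5, mild 5–15, moderate 15–30, severe ≥ 30,
with a clinical screening cutoff at AHI 15 for the binary
normal-to-mild vs. moderate-to-severe decision. All class boundaries are
half-open `[lo, hi)`: an AHI of exactly 5, 15 or 30 falls in the higher
class, consistent with a cutoff of 15 placing 15 in the
moderate-to-severe group.

The pipeline predicts these labels from three non-invasive feature
families: a 34-index heart-rate-variability (HRV) profile computed from
beat-to-beat RR intervals, two overnight oximetry summaries, and five
anthropometric attributes.

## RR-interval cleaning

Spurious beats (ectopy, misdetections) are detected against a baseline
estimated by a centered moving median of width `W` beats; a tolerance band
extends `T × mean(baseline)` above and below it. Out-of-band beats are
replaced by linear interpolation between the nearest in-band neighbors;
runs of consecutive out-of-band beats are replaced as a block, and a run
touching a series edge is anchored on the single available in-band side.
A series needing more than 2.5% replacements is ineligible for analysis;
the bound is applied per 15-minute segment (the alternative — per whole
recording — is a plausible reading, but per-segment is the stricter and
more local interpretation).

`W = 11` beats and `T = 0.2` are package defaults (typical moving-median
HRV cleaning settings; both exposed in config and marked `assumed`). The
correction behaves consistently across `W ∈ {7, 11, 21}` in the tests.
Edge beats use a shrunken window so the series length is preserved.

Interpolation recovers the *shape* of the tachogram, not its unpredictable
beat-to-beat noise: on a smooth oscillatory series with small measurement
jitter, ≥ 99% of beats are recovered to within 1 ms under 2% contamination,
whereas on an i.i.d.-noise series the corrupted 2% cannot be reconstructed
below the noise scale by any interpolator. The tests therefore check
recovery on the smooth benchmark and, separately, full detection coverage
(every injected artifact flagged, no clean beat altered) on the noisy one.

## Segment selection

One 15-minute window is taken from each of the first six recording hours.
Quality assessment is automated: candidate windows start every 60 s inside
the hour, windows never cross hour boundaries, the score is the fraction
of out-of-band beats before correction, and ties go to the earliest
offset. This replaces manual visual inspection with a reproducible
criterion. Subjects with less than six hours (or an hour shorter than
15 minutes) are excluded as "insufficient time".

## Linear HRV indices

MeanRR, SDNN (sample SD) and RMSSD in the time domain. For the spectrum,
the tachogram (RR value against cumulative beat time) is cubic-spline
resampled at 3 Hz and analyzed by Welch's method: 512-sample segments, 50%
overlap, per-segment mean removal, Hann window with power compensation
(division by the mean squared window, which makes the integrated spectrum
match the signal variance — verified to 5% in the tests). Band powers
integrate the averaged spectrum over VLF (0.003–0.04 Hz), LF
(0.04–0.15 Hz) and HF (0.15–0.4 Hz). The VLF lower bound of 0.003 Hz is a
package choice (config-exposed). Normalized units use the LF+HF
denominator, `LFnu = 100·LF/(LF+HF)`, so `LFnu + HFnu = 100` holds exactly.
No detrending beyond per-window mean removal is applied.

## Nonlinear HRV indices

* **DFA α1** — integrate the mean-centered series; window sizes n = 6…14
  (the short-range scaling band 5 < n < 15), non-overlapping windows with
  the tail discarded, linear detrending, α1 = log-log slope of F(n).
* **SampEn** (m = 2, r = 0.15·SD, Chebyshev) — −ln(A/B) over template pairs
  without self-matches; the same N−m−1 templates are used at both lengths.
  Constant input → 0 by convention; no match at length m → missing.
* **FuzzyEn** (m = 2, r = 0.15·SD, exponent n = 2) — locally centered
  templates and exponential membership exp(−(d/r)^n). The SD scaling of r
  (shared with SampEn) makes both invariant to amplitude rescaling.
* **DispEn** (m = 3, nc = 6) — normal-CDF mapping to nc classes, Shannon
  entropy of dispersion patterns, normalized by ln(nc^m).
* **PermEn** (m = 3) — ordinal-pattern entropy normalized by ln(m!), with
  deterministic tie-breaking noise of amplitude 1e-6·SD from a fixed
  per-call seed (ties are measure-zero in clean data but common in
  quantized recordings).
* **PhaseEn** (k = 16) — Shannon entropy (normalized by ln k) of the
  angle-sector occupancy of the second-order difference plot; origin
  points carry no angle and are dropped.
* **DistEn** (m = 3, M = 512) — base-2 Shannon entropy, normalized by
  log2 M, of the M-bin histogram of inter-template Chebyshev distances.
* **AttEn** — mean of the four base-2 Shannon entropies of the intervals
  between local-extrema key patterns (max–max, min–min, max–min, min–max);
  an empty interval stream contributes 0.
* **Symbolic Max–Min** — six equal-width amplitude bins over [min, max],
  3-symbol words classified 0V/1V/2LV/2UV; missing for a zero-range series.
* **Symbolic binary** — symbol 1 for an increase, 0 otherwise (a zero
  difference counts as non-increase, keeping the alphabet binary); words
  classified by number of symbol changes (0V/1V/2V).
* **Fragmentation (HRF)** — ternary difference symbols; *every* transition
  between two different consecutive symbols counts as an inflection point,
  including transitions to or from 0. PIP is the inflection percentage
  among all transitions; 4-symbol words are classified by internal
  inflection count (W0–W3).
* **Asymmetry** — Porta (% negative among nonzero differences), Guzik
  (% of squared-difference energy from positive differences), Ehlers
  (Σd³ / (Σd²)^{3/2}).
* **AC/DC** — phase-rectified signal averaging with half-window L = 8
  beats and a 5% anchor filter (both config-exposed package choices);
  capacity is the 4-point Haar-like difference
  (X(0) + X(1) − X(−1) − X(−2))/4 on the anchor-aligned average.

Degenerate-input conventions: a constant series yields 0 for
SampEn/FuzzyEn/PermEn/DispEn (the limiting value) and missing for
DistEn/PhaseEn/AttEn and the Max–Min symbols (no limit exists).

Where an estimator admits several published normalizations (DispEn,
PermEn, DistEn, PhaseEn, AttEn), the package pins one — stated above — and
the test-suite oracles are written against the same convention;
cross-study comparability of absolute entropy values therefore requires
checking the normalization, as it always does with these indices.

## Oximetry indices

SatMin is the pointwise minimum saturation; T90 is the percentage of
samples strictly below 90%. Total sleep time is the trace duration (no
hypnogram). CSV (`t`, `sat`) is the interchange format.

## Synthetic cohort generator

Every severity class is parameterized by a `SeverityEffects` block: AHI
range, cyclic-oscillation amplitude (ms) and period (s), white beat-to-beat
SD (ms), desaturation rate (fraction of AHI, or a fixed hourly rate),
desaturation depth (%), and anthropometric centers (BMI and age medians,
male fraction). Defaults reproduce the *direction* of the clinical
contrasts between severity groups — higher BMI/age/T90 and lower SatMin
with increasing severity, desaturation rate proportional to AHI — centered
on values typical of published severity cohorts.

The RR model per hour is
`base + respiratory (0.25 Hz) + baroreflex-like (0.095 Hz) + cyclic + noise`,
where the cyclic term is an amplitude-modulated sinusoid with a 45-s
period, placing its power in the VLF band the way periodic apnea-linked
breathing does. Its class-level amplitude grows with severity
(5/18/32/55 ms) while the white SD shrinks slightly (30→20 ms). Each
subject draws lognormal multipliers (σ = 0.25 for the amplitude, σ = 0.15
for the white SD) so individuals of a class overlap with their neighbors;
without this heterogeneity every model is trivially separable. The
modulation is evaluated on the nominal beat grid (the sub-second phase
error against true cumulative beat times is negligible at a 45-s period).
Artifacts are isolated beats at 0.5× or 1.5× the local value, at a
configurable rate (default 1%).

SpO2 is a 95–98% baseline with square desaturation dips (duration
15–45 s, depth drawn per class, rate per hour 0.6 × AHI), measurement
noise of 0.3%, clipped to [40, 100].

A `null_effects()` helper switches severity effects off: all classes share
one signal parameterization and a fixed desaturation rate, so only the AHI
label differs between classes. This is the null arm of the classification
calibration.

What the generator does **not** emulate: sleep-stage structure, arousals,
true ectopy morphology, respiratory-event clustering, sensor dropouts, or any
quantitative claim about how HRV indices map to AHI in patients. Passing
tests therefore demonstrate correctness and calibration of the *pipeline*,
not clinical performance; the headline AUROCs on synthetic cohorts are
properties of the generator's effect sizes, not estimates of real-world
screening accuracy.

## Classification experiments

One feature row per subject: each HRV index averaged over the six
segments, SatMin, T90, gender (male = 1, female = 0 — an arbitrary,
documented encoding), age, height, weight, BMI. Subjects with a failed
segment are excluded and logged by reason, mirroring a clinical exclusion
flow (categories: corrupted, poor quality, insufficient time, underage,
missing data).

The learner is a 100-tree random forest without depth limit under
stratified 10-fold cross-validation. SMOTE (k = 5 nearest same-class
neighbors, Euclidean distance on standardized features, interpolation in
the original space) balances every class to the majority count — applied
**inside the training folds only**, so no synthetic row ever reaches a
validation fold; a structural test spies on the oversampler to prove it.
Out-of-fold class probabilities are pooled; AUROC is one-vs-rest per class
(multiclass) or single (binary), with 95% percentile-bootstrap CIs from
2,000 subject-level resamples. Degenerate bootstrap draws (one class
absent) are redrawn implicitly by NaN-exclusion. Feature importances are
impurity decreases from a forest on the full SMOTE-balanced table,
expressed as percentages (a full-data fit is a reproducibility caveat:
importances are not out-of-sample quantities).

Model comparisons use the fast DeLong test (midrank structural
components) for correlated AUROCs on shared subjects, two-sided, with
Benjamini–Hochberg correction across the comparison family (the family is
the three feature-set models within one task; α = 0.05).

Because severity-class importance splits among correlated features, the
importance-sanity experiment in the tests asserts family-level facts
(oximetry and VLF-oscillation readouts on top, noise features at the
bottom) rather than a single fixed ranking: with only two injected
mechanisms, T90 ranks top-3 overall and first among oximetry +
anthropometric features, VLFabs ranks in the top 10, and no anthropometric
column reaches the top 20.

## Problem sizes and determinism

The test suite and the acceptance script use a 60-subject-per-class
cohort for the signal arm, twenty 10-subject-per-class cohorts for the
null arm, 20 seeds for the DFA limit checks, and 20 random 100–300-beat
series per estimator for oracle agreement — sizes at which every check is
statistically decisive while the full suite completes in minutes on one
CPU. All randomness flows from explicit integer seeds; identical
spec + seed reproduces cohorts, feature tables and model reports
byte-for-byte.

## Known limitations

* The generator's parameter defaults are engineering choices, not fitted
  physiology; effect sizes were fixed by design, and synthetic AUROCs say
  nothing about clinical accuracy.
* The EDF route is out of scope; the pipeline starts at exported RR-series
  CSVs.
* The 2.5% eligibility rule is enforced per segment; recordings judged per
  whole night would be admitted/excluded slightly differently.
* Impurity-based importances are biased toward high-cardinality continuous
  features and split credit among correlated ones; rankings should be read
  family-wise.
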