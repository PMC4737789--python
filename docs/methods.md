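# Methods

This note documents the models, numerical choices and limitations of the
package, in the order of the processing pipeline.

## Signal model and quality gating

Recordings are single-channel phonocardiograms, normalised to [-1, 1] on
read (integer WAV encodings divided by their positive full scale).  All
analysis runs at an internal rate of 8 kHz (polyphase resampling), which
puts the full 20–1000 Hz analysis band on one FFT grid.  Band-limiting is
a zero-phase order-4 Butterworth applied forward–backward; the squared
magnitude response gives ≥ 40 dB attenuation one octave outside the band
while preserving envelope timing.  Note that forward–backward filtering is
*not* idempotent for broadband noise (the second pass removes ≈ 4.8 % of
white-noise RMS in the transition bands, an analytic property of the
filter); for in-band heart-sound content a second application changes the
RMS by well under 1 %.

Three recording-level gates mirror the clinical exclusion labels, with
quantitative defaults (all config-exposed):

* **arrhythmia** — heart rate > 85 bpm (tachycardia) or RR coefficient of
  variation > 0.12;
* **excess_noise** — more than 50 % of candidate diastasis windows carry
  more than 4× the *reference* broadband envelope power.  The reference is
  the 25th percentile of window powers rather than the median: a median
  reference is itself contaminated once more than half the windows are
  noisy, which is exactly the regime the gate must detect;
* **weak_signal** — the median S1 envelope peak sits less than 6 dB above
  the background floor (the square root of the reference window power).

Gates are evaluated in that order; at least 10 cycles are required.
Breath-hold intervals, when present in the metadata, restrict analysis to
cycles fully inside a hold; otherwise all data are used (automatic
breathing-noise detection is out of scope).

## Segmentation

Cycle detection is ECG-free: the 20–200 Hz band's Hilbert envelope is
smoothed with a 20 ms Hann-weighted moving average; the beat period comes
from the envelope autocorrelation peak in the 40–120 bpm range (no
acceptable peak raises a segmentation error); peaks above 40 % of the
typical per-beat maximum (95th percentile of block maxima — gain
invariant) are picked with a 120 ms refractory distance; S1 is the peak
that starts the *shorter* intra-beat interval (systole).  S3/S4 are
searched in the 20–60 Hz envelope — S3 in early-to-mid diastole, S4 in
the 200–50 ms window before the next S1 — and marked present only when
the regional peak exceeds both 3.5× the median regional envelope level
and 5 % of the S1 low-band envelope (the absolute floor prevents spurious
detections in near-silent diastoles, where any fluctuation dominates a
tiny median).

The diastasis window runs from the end of S3 (onset + 60 ms nominal
duration; fallback without S3: S2 onset + 0.15·RR) to the S4 onset
(fallback without S4: 50 ms before the next S1).  Windows shorter than
128 ms are flagged short; a recording is short-diastasis when more than
half of its windows are.  Degenerate windows (end ≤ start) are skipped
with a log entry.  All times are seconds from recording start; windows
are half-open [start, end).

## Features

* **Mean spectrum** — per-window Welch estimate on 128 ms Hann segments
  with 50 % overlap, averaged on the linear power scale across all
  windows ≥ 128 ms, expressed in dB (floor −120 dB) on the 20–1000 Hz
  grid.
* **FPR** — log10 of low-band (20–150 Hz) over high-band (150–1000 Hz)
  total linear power.  The 150 Hz split reflects where the disease-related
  low-frequency power increase concentrates; it is config-exposed.  An
  all-floor denominator is substituted with the floor power (warning).
* **PCASpec** — the first principal axis of mean-centred dB spectra
  (SVD), unit-norm, sign-fixed so the loading's mean below 150 Hz is
  positive; the feature is the dot product of the loading with the
  centred spectrum.  One component only; fitting requires ≥ 10 spectra
  on a common grid and fails on zero-variance input.
* **AMI** — the signal is decimated to 2 kHz; amplitudes map to 16
  equiprobable (rank-based) bins; the joint-histogram mutual information
  I(x_t; x_{t+τ}) in bits is averaged over lags τ = 1..25 samples
  (0.5–12.5 ms).  Equiprobable binning makes the measure invariant to
  monotone amplitude scaling.  Constant windows return 0 by convention.
  The histogram estimator carries the usual positive bias of order
  (B−1)²/(2N ln 2) ≈ 0.04 bits at N = 4096, which cancels in
  class comparisons.
* **S4Amp** — peak of the 20–60 Hz envelope in the S4 search region,
  normalised by the median per-cycle S1 peak of the same envelope; 0 when
  the region sits below 2× the median envelope (noise floor).  This
  envelope uses lighter smoothing (8 ms) than the detection envelope so
  short transients keep their peak amplitude.

## Scoring

Fisher linear discriminants (pooled within-class covariance, ridge
1e-6 · mean-eigenvalue for numerical safety) are fitted twice: on
(FPR, PCASpec, AMI, S4Amp) for full-diastasis subjects and on
(AMI, S4Amp) for everyone (the short-diastasis branch).  The two raw
discriminants live on incommensurate scales, so each is standardised on
its training sample (mean 0, SD 1, folded into the weights); a single
shared affine calibration (slope 12, offset 25) then maps either branch
onto the population score scale, chosen to reconstruct the published
score distribution (group means ≈ 21–33, SDs ≈ 11–13).  Scores clip to
[0, 100]; categories are low (≤ 20), intermediate (20, 30], high (> 30) —
the closed-left form matches the published "NPV of a low CAD-score
(≤ 20)" usage.  How the original system mapped its discriminant to 0–100
is not published; the affine map is this package's choice.

Cross-validation is stratified k-fold, repeated with re-randomised folds
(default 20 × 10); held-out scores are pooled within a repeat and
summarised as one AUC per repeat.

The packaged default model is trained on a fixed-seed synthetic audio
cohort (40 + 40 subjects, 30 s recordings) by
`scripts/build_default_model.py`; it exists so the CLI scores recordings
out of the box and carries no clinical calibration.

## Risk models

The pre-test probability is a logistic model in age, male sex and
chest-pain type (typical / atypical / non-anginal).  The coefficient
table is configuration, not code; the shipped default is the published
updated model (intercept −7.539, age 0.062/yr, male 1.332, atypical
0.633, typical 2.244).  Probabilities map to four categories with
right-continuous boundaries: very low < 10 %, low 10–30 %, moderate
30–60 %, high ≥ 60 %.  Calcium-score groups are = 0, (0, 400), ≥ 400
Agatston units.

The combined model is an (unpenalised) logistic regression of disease on
the logit pre-test probability and the raw CAD-score — the simplest
fusion consistent with reporting a combined AUC and NRI.  Separation is
detected by saturated fitted probabilities and handled with a weak L2
penalty (C = 1000) and a warning.

## Diagnostics

AUC is the tie-corrected Mann–Whitney statistic; variance and paired
comparisons use DeLong's structural components (midrank formulation);
CIs are Wald on the AUC scale, clipped to [0, 1].  Identical paired
scores return p = 1 by convention.  The optimal cut-point maximises
sensitivity × specificity (Liu's criterion) over midpoints between
adjacent distinct scores, ties broken toward the lower threshold; Youden
is available as a config alternative.  "Positive" always means *strictly
greater* than the threshold.  Binary metrics are computed in exact
rational arithmetic before conversion to float; proportion CIs are
Wilson intervals (the published CI method for these is not stated).
NRI (categorical on the 4-level scale, continuous on any probability
change) and IDI follow the standard definitions with asymptotic normal
CIs; bootstrap CIs are out of scope.

The packaged reference reclassification table prints its non-event net
move as "20 (12 %)" while the printed up/down counts give 55 − 36 = 19
(11.5 %); the package reports the count arithmetic and flags the
one-patient discrepancy in its reproduction report.

## Simulator

**Waveform.**  Each beat is a sum of Gaussian-enveloped tone bursts:
S1 45 Hz / 70 ms, S2 90 Hz / 60 ms, S3 and S4 40 Hz / 50 ms (shapes
overridable per subject).  The landmark schedule places S2 at
S1 + 0.08 + 0.25·RR, S3 at S1 + 0.5·RR − 0.01 and S4 120 ms before the
next S1, making the diastasis length 0.5·RR − 0.17 s: every window is
≥ 128 ms below ≈ 100 bpm and short-but-positive up to ≈ 125 bpm, so both
feature branches are exercised by heart rate alone.  Disease enters
through two independent murmur gain knobs applied to diastasis-gated
band noise — low-frequency (20–150 Hz) and microbruit (200–500 Hz) —
each at −35 dB RMS re full scale at gain 0, plus a white noise floor
(default −60 dB).  Beat-to-beat RR jitter is a truncated Gaussian with
2 % SD.  Default duration 180 s with four 7.5 s breath-hold intervals
stamped in the metadata (the recording protocol); tests use 20–30 s
recordings without breath-hold restriction, which is statistically
equivalent here because no breathing noise is modelled.

**What it does not emulate:** real S1/S2 morphology variability, valve
murmurs, respiration and motion artefacts, sensor transfer functions,
and any physiological murmur spectrum — the gains are free parameters,
not hemodynamic claims.  Passing end-to-end tests therefore shows the
pipeline recovers *planted* spectral/amplitude effects, not that it
detects clinical disease.

**Cohorts.**  Patient-level CAD-scores and pre-test probabilities are
drawn per disease group (default sizes 124/41/63) from truncated-normal
margins joined by a Gaussian copula.  Two calibration choices matter:

* The published group mean ± SD are sample moments of a *bounded* score,
  so the margins are moment-matched: the truncated distribution's mean
  and SD are solved (numerically) to equal the printed values.  Naive
  truncation of N(mean, SD) would bias the non-CAD group mean upward by
  ≈ 1.3 points.
* The within-group latent copula correlation is solved so that the
  *overall* score/pre-test Pearson correlation equals the published 0.36
  after accounting for the between-group mean structure (the solved
  latent value is ≈ 0.21); an infeasible target raises an error.

Age, sex and chest-pain type are back-filled consistently with the drawn
pre-test probability: sex/pain are sampled from the group's published
frequencies *restricted to combinations that can reach the drawn
probability with an age inside [18, 110]*, and age is obtained by
inverting the logistic model.  Calcium scores are drawn per the group's
published category frequencies with log-uniform values inside each
category band (the within-band shape is a convenience choice, not a
calibration target).

**Feature-space cohorts** (for scoring tests) are two-class Gaussians in
the 4-D feature space with per-feature effect 0.57 and inter-feature
correlation 0.3, giving a discriminant AUC in the low 70s — mirroring
the score-distribution overlap of the reference cohort.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds (cohort CSVs record the
seed in a comment line).  The test suite uses 20–30 s recordings, a
40 + 40-subject audio cohort for the end-to-end planted-effect check,
200 replicate cohorts for the distribution-level AUC check and 500 for
the correlation check — sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances.  The acceptance script recomputes the
reclassification arithmetic exactly and the distribution-level AUC from
200 replicates.

## Known limitations

* The S1/S2/S3/S4 detector is original engineering validated on the
  synthetic generator; real phonocardiograms (murmurs inside systole,
  split sounds, pathological rhythms) would need a tuned or learned
  segmenter.
* The exact published formulas of FPR and PCASpec, the AMI estimator
  settings and the 0–100 calibration are not public; the implementations
  here are principled reconstructions with every constant config-exposed.
* NRI/IDI confidence intervals are asymptotic; small-sample inference
  should bootstrap.
* The packaged default model is synthetic-trained and is not a clinical
  decision tool.
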