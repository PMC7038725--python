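# Methods

This note documents the models and procedures implemented in
`stresspipe`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Preprocessing

**Windowing.** Sessions are cut into contiguous, half-open
`[t0, t0+120 s)` windows from the session start; the trailing partial
window is dropped (no padding).  Two minutes is long enough to resolve
the 0.04 Hz lower edge of the LF band while still tracking stress onset
and recovery, which play out over a few minutes.  A beat falling exactly
on a boundary belongs to the later window; windows are 0-indexed.

**RR artifact rule.** Interval *i* is flagged when
`|rr[i] − rr_ref| / rr_ref > 0.20`, where `rr_ref` is the most recent
*non-flagged* interval and the first interval is never flagged.  Using
the last clean interval (rather than the raw predecessor) prevents one
ectopic beat from flagging its normal successor.  The known costs are
accepted rather than patched: an abrupt genuine rate shift (e.g. the
stressor-to-recovery transition) can flag a run of beats until the
reference catches up, and an ectopic beat that happens to open a window
poisons the reference and cascades.  Both cases produce artifact
fractions that the 10% rejection rule then correctly discards, which is
the intended failure mode.

**Correction and rejection.** Flagged beats are replaced by a cubic
spline fitted over (beat index, RR) of the clean beats; edge beats
outside the clean support are extrapolated and clamped to the clean
range (extrapolated cubics diverge quickly).  With fewer than four clean
beats the replacement degrades to linear interpolation.  Correction is
refused — and the window invalidated — above 50% flagged.  Window
validity uses the *pre-correction* flags: a window is rejected when
strictly more than 10% of its beats are flagged (exactly 10% is kept,
i.e. 6 of 60 passes, 7 of 60 fails).

**EDA screening.** A deterministic per-epoch (5 s) rule: an epoch is
artifactual when a steep conductance change (> 0.5 µS per 4 Hz sample)
coincides with wrist motion (accelerometer magnitude SD > 0.1 g in the
epoch), or when the level leaves [0.01, 60] µS.  A sample-to-sample
change is attributed to the epoch it enters, so steps across epoch
boundaries are caught.  Without an accelerometer the screen falls back
to the EDA-only rules and warns.  The thresholds are configurable; they
were fixed once from typical SCR slew rates and wrist-motion noise
floors.  Flagged epochs are excluded from feature computation
sample-wise rather than rejecting the whole window, maximizing usable
EDA data.

**Tonic/phasic split.** Tonic = zero-phase (forward-backward) low-pass
Butterworth, order 4, cutoff 0.05 Hz; phasic = signal − tonic, so the
reconstruction is exact by construction.  SCR kinetics live well above
0.05 Hz while tonic drift lives below it.  A convex-optimization
decomposer could be plugged in behind the same `EDADecomposition`
interface, but the feature set only requires a smooth/fast split, and
the filter is testable in closed form.

## Features

All features are computed per window and averaged per session
(arithmetic mean, missing entries excluded feature-by-feature, so a
window missing one modality still contributes the other).

*Time-domain HRV* (on corrected RR, ≥ 10 intervals): mean RR; SDNN and
SDSD with the n−1 denominator; RMSSD; pNN50 as a percentage of
successive differences exceeding 50 ms.  The *triangular index* is
n / (modal bin count) of the RR histogram with 1000/128 ms bins aligned
at zero — "height of the histogram" is read as the modal bin count, the
standard geometric definition.  *TINN* is the base width of the best
least-squares triangle fit to that histogram: the apex is pinned to the
modal bin, base endpoints are searched on the bin grid (one bin beyond
each end included) and ties prefer the narrowest triangle, so a
single-bin histogram gives TINN = 0.

*Frequency-domain HRV* (≥ 60 s of beats): the (beat time, RR) tachogram
is cubic-spline resampled at 4 Hz, mean-removed, and an un-windowed FFT
periodogram is integrated by the rectangle rule over half-open bands —
VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz — with the DC bin
excluded.  With this estimator the band powers sum exactly to the
resampled signal's variance (Parseval), which the tests exploit.  Band
peaks are the frequency of the maximum ordinate within the band; LF/HF
and peaks are reported missing (NaN), never infinite, when the
denominator band is empty.  Spectra are per-window and then averaged,
like every other feature.

*EDA per component* (phasic and tonic separately): mean, SD, number of
peaks (prominence ≥ 0.01 µS, ≥ 1 s apart), number of strong peaks
(prominence ≥ 0.10 µS), 20th and 80th percentiles
(linear-interpolation dialect) and quartile deviation (p75 − p25)/2.
The two prominence levels follow common SCR amplitude conventions
(detection floor vs. clearly supra-threshold responses).

## Labeling

PSS-5 items H, C, A, S, F each range 1–6; the score is
`(7−H) + (7−C) + A + S + F`, reverse-keying the positive-affect items.
The attainable range is therefore [5, 30] even though the nominal scale
is quoted as 0–30; the formula is applied as defined.  Binarization:
score < 15 → relaxed, ≥ 15 → stressed (the boundary value is stressed;
configurable).  Known-context labels map baseline → relaxed and
stressor → stressed; recovery is excluded from the two-class context
task because the contrast of interest is stress vs. baseline, not
post-stress recovery.  Sessions with missing self-reports are dropped
from self-report datasets with a logged reason.

## Modeling

Session-level vectors are pooled across participants into one general
model (no per-participant models).  Each cell applies, on training data
only: exact-balance random undersampling of the majority class;
correlation-based feature selection (rank by |point-biserial
correlation| with the binary label, ties broken by schema order;
defaults k = 10 combined, 5 per single modality; a CFS best-first
subset search on the standard merit
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` is available); and per-feature
min-max scaling to [0, 1] (test values may leave the interval; constant
training columns map to 0).

Classifiers: MLP with two hidden layers of five units (adam, ≤ 500
epochs), random forest with 100 trees, 3-nearest-neighbors, RBF-kernel
SVM (library defaults C = 1, gamma = "scale", recorded in the run
manifest), and logistic regression thresholded at 0.5.

Evaluation: stratified 10-fold CV (accuracy = mean over folds, fold SD
with n−1; the pooled-confusion accuracy can differ from the fold mean
by less than one rounding unit when folds are unequal), a stratified
80/20 split, and cross-environment transfer (fit entirely on one
environment, scored once on the other; the test environment's
self-reports are always the scoring labels).  By default undersampling,
selection and normalization are re-fit inside each training fold; the
conventional global order — which leaks test information into
preparation — is available behind `global_prep=True` for comparability.

The five-way matrix crosses environment with ground-truth family:
LLKC and LLSR (lab, CV + split), DDSR (daily, CV + split), LDKC and
LDSR (lab-trained, daily-tested transfer) × three modalities × five
classifiers.  Cells that are impossible on a given dataset (missing
label family, too few rows per class for the fold count) are skipped
with a logged reason rather than silently filled.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not
cardiac or sudomotor physiology:

* **RR**: `rr(t) = rr_mean(state) + lf_amp·sin(2π·0.10·t) +
  hf_amp·sin(2π·0.25·t) + N(0, 15 ms)`, beats accumulating RR
  durations.  Defaults: relaxed 850 ms mean, LF/HF amplitudes 30/40 ms;
  stressed 700 ms, 40/15 ms — i.e. stress shortens RR, cuts HF
  modulation to roughly a third and flips LF/HF above 1.  A
  sinusoid-plus-noise model (rather than integral-pulse frequency
  modulation) was chosen because its band powers are analytically
  known, letting the spectral features be verified in closed form.
* **EDA**: state-dependent tonic level (2.0 µS relaxed, 4.0 µS
  stressed) plus a slow random walk (0.003 µS/sample), plus
  Poisson-arriving SCRs (2/min relaxed, 8/min stressed; amplitude
  uniform 0.1–0.6 µS) with bi-exponential kinetics (rise 0.75 s, decay
  2.0 s, unit-peak normalized).
* **Artifacts** (defaults: 2 per 100 beats, 0.5 per minute): isolated
  RR beats scaled by 0.5 or 1.5–2.0 — always past the 20% rule — and
  EDA steps/spikes with co-occurring accelerometer bursts, all recorded
  in a ground-truth mask.
* **Self-reports**: items drawn from state-consistent distributions
  (relaxed scores 5–12, stressed 20–30) flipped to the opposite state's
  distribution with probability 0.05 (lab) / 0.20 (daily).  The daily
  flip rate is a free simulation parameter — field label noise is not
  quantified anywhere — chosen as a plausibly large recall-bias level;
  the lab/daily asymmetry is the point, not the exact values.
* **Study layout**: 12 participants; one lab session each of three
  240-s phases (baseline/stressor/recovery), every phase
  context-labeled and self-reported; four 600-s daily sessions each
  with a self-report only.  Daily latent states are stressed for an
  exact 27% of sessions (randomly placed), mirroring the canonical
  field imbalance.  Durations are scaled down from hour-scale field
  sessions so that the full matrix evaluates in tens of seconds; the
  latent state and artifact masks are exposed for test oracles only.

What passing tests on this generator shows: the pipeline's rules,
features and evaluation machinery are correct, leak-free and calibrated
(permuted labels score at chance), and the qualitative
cross-environment ordering (LDSR above DDSR under asymmetric label
noise) follows from the assumed mechanism.  What it does not show:
performance on real wrist data — real PPG beat detection errors,
activity confounds, thermoregulatory EDA drift and participant
heterogeneity are all absent, and session counts are far smaller than a
real cohort's.

## Degenerate inputs and tie-breaks

Constant RR gives zero variability features, triangular index 1,
TINN 0, empty spectra and a missing LF/HF.  Fewer than 10 corrected
intervals, under 60 s of beats, or under 30 s of clean EDA drop the
affected modality for that window with a warning; a unit with no valid
window is dropped with a logged reason.  Feature-selection ties keep
schema order; TINN ties keep the narrowest triangle; the histogram mode
takes the lowest bin on ties (NumPy argmax).  All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
byte-identical datasets and evaluations.

## Known limitations

The EDA artifact screen is a deterministic rule, not a trained
classifier; it is tuned to the generator's artifact model and real-data
thresholds would need recalibration (a retrainable hook accepts labeled
epochs).  The tonic/phasic split is a linear filter and will leak very
slow SCR trains into the tonic component.  TINN's exhaustive grid
search is O(bins²) per window — fine at 2-minute windows, slow for
hour-long single windows.  Transfer evaluation assumes the two
environments share the feature distribution's support; no domain
adaptation is attempted.
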