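# Methods

## The problem

Consumer-grade EEG headsets make it practical to record children's resting
brain activity in schools, but it is unclear whether they measure the
*aperiodic* (1/f) component of the EEG — a proposed marker of cortical
excitation/inhibition balance — as reliably as research-grade laboratory
systems. `aperio` implements the complete comparison pipeline for this
question: spectral parameterization, split-half reliability, bootstrap
equivalence testing of fit quality, signal-quality metrics, cross-validated
predictability of the aperiodic estimates, and the association between
aperiodic activity and arithmetic fluency. Because no real recordings ship
with the package, every stage is exercised against a synthetic-cohort
generator with known ground truth; what the tests show is therefore
recovery and calibration under the generator's assumptions, not validation
on real EEG (see *Limitations*).

## Spectral model

The power spectrum over 1–40 Hz is modeled in log space as an aperiodic
line plus Gaussian peaks:

    log10 P(f) = b − χ·log10 f + Σᵢ PWᵢ · exp(−(f − CFᵢ)² / (2σᵢ²)),  σᵢ = BWᵢ/2

* `b` — offset, log10(µV²/Hz) at 1 Hz (log10 f = 0).
* `χ` — exponent, the magnitude of the log-log slope (χ ≥ 0; flatter
  spectra ↔ larger excitation/inhibition ratio).
* `(CF, PW, BW)` — peak center (Hz), height (log10 power), and bandwidth
  (Hz, defined as 2σ), clamped to BW ∈ [1, 8]; at most 5 peaks; no knee
  term.

Fitting (`spectral.fit_spectrum`):

1. Robust seed fit of the aperiodic line by least squares on
   (log10 f, log10 P); the top 2.5% positive residuals are discarded and
   the line refit, so narrow peaks cannot drag the seed slope too far.
2. Iterative peak extraction on the flattened spectrum: take the largest
   residual maximum, fit one Gaussian around it (σ bounded by the width
   limits, width guess from the residual's half-height span), subtract,
   repeat. Iteration stops at the peak cap or when the residual apex falls
   below max(2.0 × SD(residual), minimum height, 1e−6). The absolute
   1e−6 floor exists so that machine-precision residuals on exact
   power-law input are never fit as peaks.
3. Aperiodic refit on the peak-stripped spectrum.
4. One refinement round: peaks are re-derived from the refined aperiodic
   fit and the line refit once more. This removes the residual slope bias
   a large alpha peak exerts on the seed fit; on noiseless analytic
   spectra the refined parameters land within 10⁻² of truth (verified in
   the acceptance suite), which a single pass does not reliably achieve.

Fit quality follows the parameterization-tool convention: R² is the
squared Pearson correlation between modeled and observed log10 power over
the fit range (stated explicitly because "R-squared" is ambiguous), MAE
the mean absolute log10-power error. The *aperiodic composite* — the
brain variable used for brain–behavior analysis — is the unweighted mean
of {offset, exponent} at channels F3 and F4, averaged on their natural
(unstandardized) scales, exactly as the source analysis defines it.

PSDs come from Welch's method: Hann taper, 1024-sample windows, 75%
overlap, one-sided density scaling, computed on the retained (artifact-
free) samples. At 128 Hz this gives a 0.125 Hz grid. Research-grade
recordings (512 Hz) are reduced to 128 Hz with a polyphase anti-alias
filter before spectral analysis so both systems share one grid.

## Synthetic cohorts

`synth` generates two cohorts emulating the study design: n = 93 children
on a consumer 128 Hz profile and n = 52 on a research 512 Hz profile,
4 minutes of eyes-open rest at F3/F4.

**Signal synthesis.** Random-phase spectral shaping: the amplitude
spectrum is √(target PSD) with uniform random phases, inverse-FFT'd to a
time series. The expected periodogram then equals the analytic model
spectrum exactly, so `oracle_psd` is a clean oracle for every downstream
estimate. Device nuisance terms are added per profile:

| term | consumer | research | rationale |
|---|---|---|---|
| 50 Hz line sinusoid | 2.0 µV | 0.4 µV | unshielded vs. shielded leads |
| ~32 Hz harmonic bump (σ = 1.5 Hz) | 1.0 µV RMS | 0 | consumer hardware/monitor harmonic |
| <1 Hz drift (half-Gaussian PSD, σ = 0.35 Hz) | 6 µV RMS | 1.5 µV RMS | electrode drying/movement |
| artifact bursts (±500 µV, 1 s, Poisson) | rate 0.04/segment | 0.01 | motion artifacts |

Bursts are zero-mean ±500 µV square waves inside their 1 s window (a
unipolar pulse would smear through the 0.1 Hz zero-phase high-pass into
neighboring segments and be rejected far beyond its true extent); burst
locations are recorded in ground truth so segment rejection is testable.

**Population parameters.** Per subject: offset ~ N(0.5, 0.4) in
log10(µV²/Hz), exponent ~ N(1.3, 0.25) truncated at 0.3, correlated 0.6
with the offset; one alpha peak with CF ~ N(9, 1) Hz, PW ~ N(0.5, 0.15)
(floor 0.1), BW ~ N(2, 0.4) clipped to [1, 6]. No published
distributional parameters exist for frontal aperiodic activity in 9–10-
year-olds; these values are plausible for children (higher offsets and
steeper slopes than adults, alpha still below the adult 10 Hz) and are
fixed conventions of the generator, chosen once.

**Split-half stability knob.** Each recording is built as two contiguous
halves whose standardized parameters follow v_h = √ρ·T + √(1−ρ)·e_h with
subject-stable T, so the cross-half correlation of each true parameter is
exactly ρ_half (default 0.9). A perfectly estimated parameter therefore
has split-half ICC ≈ ρ_half; estimation noise attenuates it slightly.
F3/F4 share 90% of the latent variance.

**Behavior.** The math score is math_z = r·x_z + √(1−r²)·ε against the
ground-truth composite (default r = −0.23), rescaled to mean 101.97,
SD 27.57, rounded and clipped to [0, 200]. Clipping and rounding
attenuate the realized correlation by well under 0.01 at these settings;
the unclipped `math_raw` column is retained so calibration tests can
measure the pre-clip correlation. Working-memory proportions are built
against the *math* score (correlation 0.3, clipped to [0, 1]), which
reproduces the observed pattern of math–WM correlations ≈ 0.3 alongside
near-zero composite–WM correlations (≈ r·0.3).

**Seeding.** One master `SeedSequence` spawns per-subject streams, so
subject k's recording is invariant to cohort size, and every bootstrap
takes an explicit seed recorded in the reports.

## Preprocessing

0.1 Hz 4th-order Butterworth high-pass (applied as second-order sections)
and a 50 Hz IIR notch (Q = 25), both forward–backward so the phase
response is zero and filter delay cancels. Segment rejection drops 1 s
segments whose peak |amplitude| exceeds 100 µV on any analysis channel —
a threshold stand-in for the manual, ICA-assisted screening used on real
data. Subjects are excluded when more than 25% of the recording is
discarded; exactly 75% retention is kept (strict "more than" reading).
After downsampling, the retained mask is eroded by the anti-alias
filter's half-width (11 samples at 128 Hz) so burst energy smeared by the
FIR cannot leak into retained data. Quality band powers (49–51 Hz line
noise, 0.1–1 Hz drift; means of log10 power with inclusive band edges)
are computed on the filtered data, matching the source analysis.

## Statistics

**ICC(2,1).** Single-measure, absolute-agreement, two-way random-effects
intraclass correlation on the n × 2 matrix of half-wise estimates:
ICC = (MS_R − MS_E) / (MS_R + MS_E + (2/n)(MS_C − MS_E)); 95% CI by the
McGraw & Wong (1996) F construction. The implementation is closed-form
over stacked matrices so the ΔICC bootstrap (subjects resampled with
replacement independently within each system at its own n, 10,000
resamples, percentile CI, two-sided percentile p) runs vectorized.
Degenerate resamples (zero between-subject variance) are redrawn and
counted.

**Equivalence (TOST logic).** The consumer-minus-research mean difference
of each fit-quality metric is bootstrapped (10,000 resamples, each group
at its own n); equivalence against the pre-declared bound ±Δ
(MAE: 0.0075, R² F3: 0.0102, R² F4: 0.0091) is concluded exactly when
the 90% percentile CI lies inside [−Δ, +Δ] — equivalent to two one-sided
5% tests. Percentile endpoints use the linear-interpolation order-
statistic convention throughout the package. Shapiro–Wilk results are
reported as the normality gate that motivates the nonparametric route;
a plain t-test is available (`equivalence.welch_t_test`)
but not part of the headline report.

**Cross-validation.** Full-recording fits are melted to one row per
subject × channel-component cell (F3_offset … F4_exponent), IQR outliers
(k = 1.5, per cell) removed, then split 80/20 stratified by cell. The
regressors see only one-hot categorical features, so the training-fold
cell-mean predictor is Bayes-optimal under squared loss and serves as the
floor; the Gaussian process (RBF + white kernel over the one-hot space,
hyperparameters by marginal likelihood) and random forest must match it
within sampling noise. Error sensitivity recomputes MAE after dropping
the 3 largest absolute errors plus Tukey-severe outliers
(Q3 + 3 × IQR of the remaining absolute errors) and reports the 95%
percentile bootstrap CI of the change. Note the ΔMAE plug-in is
non-negative by construction: its CI collapses onto 0 for homogeneous
(equal-magnitude) error sets and moves strictly above 0 when a few
extreme errors inflate the MAE; trimming effects below 10⁻⁹ of the mean
absolute error are snapped to zero to keep the degenerate case exact in
floating point.

**Association.** Pearson r with the two-sided t-test p and the
Fisher-transform CI atanh(r) ± 1.96/√(n−3) (the CI method is fixed here
because several conventions reproduce published intervals only to
±0.01). Correlations between cohorts are compared with Fisher's
Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). The supplementary
simple mediation fits m~x, y~x+m, y~x by OLS on z-standardized variables
(so c = c′ + a·b holds identically) with a 5,000-resample case bootstrap
percentile CI for a·b; the bootstrap path uses the closed-form normal
equations for speed and is exact OLS.

## Problem sizes in the validation studies

The acceptance/validation studies (`aperio.validation`, run by
`scripts/acceptance.py` and the headline test suite) use these sizes,
chosen to keep Monte-Carlo error small on a single CPU:

* fit oracle sweep: 27 analytic spectra (b ∈ {−2,0,2} × χ ∈ {0,1.5,3} ×
  {0,1,2} peaks);
* parameter recovery: 50 subjects per profile, 240 s recordings;
* ICC consistency: 50 replicates of n = 2,000 at true reliability 0.5
  and 0.9;
* TOST operating characteristics: 1,000 replicates (n = 100/group) at
  the bound, 400 replicates (n = 400/group) at zero difference, B = 1,000
  inside each replicate;
* reliability pattern: full-pipeline cohorts of n = 80 at ρ_half 0.95 and
  0.30; ΔICC separation power over 50 parameter-level replicates
  (n = 80/group, B = 2,000);
* behavioral calibration: 500 cohorts of n = 90; Fisher-Z type-I: 1,000
  paired cohorts (n = 90 and 50);
* quality contrast: 50 paired cohorts of 6 subjects, 60 s recordings;
* cross-validation floor: 90 subjects (360 rows); sensitivity
  calibration: 200 homogeneous residual sets of n = 200.

## Limitations

* The generator has no physiological artifacts separable by ICA (blinks,
  ECG), no electrode-geometry or montage model, and stationary spectra
  within each half; passing tests demonstrate correct recovery and
  calibrated inference under these conditions, not performance on real
  recordings.
* Automated amplitude-threshold rejection replaces the manual,
  ICA-assisted cleaning used with real data; retention figures are not
  comparable to visually cleaned recordings.
* The composite averages offset and exponent on different natural scales;
  it is implemented literally as defined in the source analysis, not
  because the scales are commensurable.
* Reported cross-validation MSE/MAE are on the generator's parameter
  scale and are not comparable to values computed on other datasets or
  scales.
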