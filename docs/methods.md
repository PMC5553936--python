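# Methods

## The model

Trials are indexed by i; Yᵢ ∈ {0, 1} is the perceptual outcome and t_stimᵢ
the stimulus time in seconds relative to movement onset (negative = before).
The working hypothesis is that a movement-locked oscillation of frequency f
modulates the probability of a correct report through its phase φᵢ at the
moment the stimulus appears:

    P(Yᵢ = 1) = logit⁻¹( β₀ + β₁ sin φᵢ + β₂ cos φᵢ )
              = logit⁻¹( β₀ + κ cos(φᵢ − φ_opt) ),

with κ = ‖(β₁, β₂)‖ and φ_opt = atan2(β₁, β₂).  The two parameterizations
are identical (β₁ = κ sin φ_opt, β₂ = κ cos φ_opt); the first is what the
regressions fit, the second is what the synthetic generator draws from,
which makes (κ, φ_opt) directly recoverable.

For behavioural analyses φᵢ = 2πf·t_stimᵢ (the phase of an assumed
movement-locked sinusoid).  For EEG analyses φᵢ is measured: the epoch is
band-pass filtered (two-pass 3rd-order Butterworth, 3–5 Hz by default, so
zero net phase shift), the Hilbert transform gives the analytic signal
H(t), and the phase at an estimation time t is extrapolated to the stimulus
at constant frequency, phase_at_stimᵢ(t) = arg Hᵢ(t) + 2πf(t_stimᵢ − t).
Phase convention everywhere: cosine phase, 0 at a signal peak, wrapped to
(−π, π].

### Group-level inference

Per subject the fit yields (β₁, β₂), treated as one bivariate (equivalently
complex) observation.  With n subjects, the group null "no consistent phase
effect" is tested with one-sample Hotelling's T² = n m′ S⁻¹ m (m the sample
mean pair, S the (n−1)-denominator covariance), referred to the exact F
transformation F = ((n−2)/(2(n−1)))·T² on (2, n−2) df.  The effect size is
the predictive value PV = ‖m‖, with a leave-one-subject-out jackknife SE,
SE² = ((n−1)/n)·Σᵢ(PVᵢ − P̄V)².  This test is significant only when the
per-subject effects are both large and aligned in phase across subjects —
a rotation of all subjects' effect vectors by a common angle leaves T² and
PV unchanged.

Maps over channels × estimation times (−1.9 to 0 s, step 0.025 s) are
corrected by Benjamini–Hochberg FDR over the full channel × time family; a
time point counts as significant when at least one channel survives.
Single-time control variants (forward-only, pre-movement stimulus-locked)
are corrected across channels only.  Condition contrasts (short vs long
instructed interval) permute each subject's condition labels of the
complex effects (1000 permutations, statistic |PV_short − PV_long|,
add-one p-value convention, minimum attainable p = 1/(n_perm+1)).

### Phase locking

MRV_c(t) = (1/n)Σᵢ H_ic(t) is the amplitude-weighted mean resultant vector;
dividing each trial by |H_ic(t)| first gives the inter-trial coherence.
The split-half statistic avoids both subject-specific topographies and the
channel × time correction burden: trials are split into two random halves,
MRVs computed per half, and the two channel-vectors correlated by the
complex inner-product correlation r(t) (|r| ≤ 1 by Cauchy–Schwarz).  Under
no locking, the halves' MRV phases are independent and E[Re r(t)] = 0;
genuine movement-locked phase alignment forces the halves to share phases,
making Re r(t) > 0.  Re r(t) (not the complex mean, which is also exposed
for diagnostics) is averaged over 500 random partitions per subject, then
tested against zero across subjects with a one-sample t-test and BH-FDR
across time.  With an odd trial count one trial is dropped uniformly at
random per partition.

### Behavioural spectra

The random-effects spectrum fits the sin/cos logistic model per subject at
2.5–14.5 Hz (step 0.5) and applies the Hotelling test per frequency,
uncorrected across frequencies.  The fixed-effects route bins pooled
percent correct over [−0.575, 0.475] s (bin 0.05 s, step 0.025 s — each
interior trial contributes to two bins), demeans, Hanning-tapers, and
zero-pads the series to 80 samples so the FFT lands exactly on the 0.5 Hz
grid; the permutation null re-pairs stimulus times and outcomes (the
multiset of each is preserved), and p per frequency is the proportion of
surrogate powers ≥ observed, BH-FDR corrected across frequencies.
Demeaning before tapering is deliberate: a constant performance level then
has identically zero power at every analysis frequency.  Bins with fewer
than 5 trials are linearly interpolated for the FFT path and flagged.

## The synthetic generator

The generator emulates the study conditions the analyses assume:

* movement time per trial ~ Normal(instructed, SD) truncated positive, with
  instructed intervals 1.5 s (short) and 2.3 s (long) from cue offset and
  SDs 0.2 / 0.24 s (the empirically observed onset-time spreads);
* stimulus time uniform in [−0.35, +0.25] s around the *instructed*
  movement time, then re-expressed relative to the produced onset — this
  reproduces the dense, roughly movement-centred stimulus sampling;
* EEG epochs (default −2.9 to +1.0 s at 500 Hz) = unit-RMS 1/f Gaussian
  background (spectrally shaped white noise, exponent 1) scaled by a noise
  amplitude, plus movement-locked bursts env(t)·cos(2πf t + θ₀), Gaussian
  envelopes with configurable center/width/amplitude and optional per-burst
  per-trial phase jitter (jitter 0 = perfectly locked; independent jitter
  per burst de-couples early and late phases).  The default two-burst
  profile (−1.4 s and −0.05 s) mimics a non-monotonic early/late locking
  profile.  The oscillation's phase at movement onset is θ₀, so the latent
  phase at the stimulus is θ₀ + 2πf·t_stim — the same convention the
  measurement chain uses, which is the closure property that makes
  parameter recovery meaningful;
* outcomes ~ Bernoulli(logit⁻¹(β₀ + κ cos(φ − φ_opt))) on the latent phase,
  defaults β₀ = logit(0.75) (threshold-level performance), κ = 0.8;
* force traces: flat holding baseline, then a quadratic rise from the onset
  sample — the 15-consecutive-positive-difference onset rule recovers the
  configured onset exactly.

What it does not emulate: volume conduction and realistic topographies,
artifacts (eye, muscle, line noise), non-stationary background spectra,
learning/fatigue trends, and any coupling between movement-time variance
and perception.  Passing tests therefore demonstrate the *statistical
machinery* is correct and calibrated, not that real EEG satisfies the
model's assumptions.

## Numerical choices

* **Logistic solver.**  The per-cell fits (3 or 5 coefficients, tens of
  thousands of cells) use a Newton–Raphson solver vectorised over a batch
  axis, step-capped at 5 per sweep for stability, converged when the score
  drops below 1e−10.  Coefficients beyond |β| = 15 are declared separated
  (the MLE diverges) and flagged non-converged; cells with one-class
  outcomes or fewer than 30 trials (configurable) are not fitted.  Fits are
  cross-checked in the tests against statsmodels' Binomial GLM and an
  independent nested grid-search ML oracle (agreement < 1e−3).
* **Filtering edges.**  Band-pass and Hilbert run on the longest available
  epoch; the analysis window ([−1.9, 0] s) is cut afterwards, keeping edge
  artifacts outside.  Epochs must extend ≥ 6 cycles of the low band edge.
  The complex analytic signal (not the phase) is resampled to 200 Hz by
  polyphase filtering; for in-band signals the difference from resampling
  phases is below 0.02 rad.
* **Degenerate inputs.**  A subject set whose effects are a point mass at
  zero is the exact null (T² = 0, p = 1); a nonzero point mass raises a
  singular-covariance error.  Zero-amplitude samples are excluded from
  normalized MRVs; zero between-subject variance makes the locking t-test
  degenerate (flagged, excluded from the FDR family).  PV = 0 leaves
  φ_opt undefined (nan).
* **Permutation conventions.**  Condition contrasts count ties as
  exceedances and add one to numerator and denominator; the behavioural
  FFT permutation reports the plain proportion of surrogates ≥ observed,
  so a constant series yields p = 1 exactly.
* **FDR and localization.**  BH-FDR controls the expected false-discovery
  *proportion*; when a map contains many true rejections, a small number
  of false cells passes by construction.  Localization claims in the tests
  are therefore assessed at distant control epochs (e.g. −1.4 s when the
  burst is at −0.05 s), not as zero leakage anywhere.

## Problem sizes and defaults in the validation suite

Test and acceptance runs use desk-scale problem sizes chosen as the
package's own trade-off between statistical resolution and runtime:
17 subjects × 150 trials × 3 channels at 500 Hz for end-to-end closure
(50 frozen replicates in the tests, 20 seeded replicates in the acceptance
script), estimation times every 0.1 s, burst amplitude 2 against background
noise 3 (single-trial burst SNR ≈ 0.7) for phase-prediction runs and noise 8
(SNR 0.25) for phase-locking localization — the locking statistic is far
more sensitive than the prediction chain, and at higher SNR the filter
ringing of a locked burst is itself detectably locked well away from the
burst.  The behavioural permutation test runs 1000 permutations in the
validation suite (5000 is the analysis default).  Hotelling calibration
uses 10⁴ null datasets of 17 subjects.

## Known limitations

* Extrapolation assumes a constant oscillation frequency f; real theta
  drifts, so predictive value decays with |t_stim − t| faster in data than
  in the constant-frequency simulator.
* Narrow-band filtering smears bursts over several hundred milliseconds;
  apparent phase information adjacent to a genuine burst epoch is expected
  and is why forward-only and stimulus-locked controls exist.
* The Hotelling reference assumes approximate bivariate normality of
  per-subject coefficients; with very few trials per subject the
  coefficient noise is heavy-tailed and calibration degrades.
* Trial filtering and the minimum-trials rule interact in the forward-only
  variant near t = 0, where most stimuli have already appeared; cells
  failing the rule are masked, not fitted.
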