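# Methods notes

This document records the models behind `thetawm`, the parameters that
matter, the numerical choices made where conventions were genuinely open,
and what the synthetic validation does and does not establish.

## Synthetic EEG generator

**What it emulates.** Epoched sensor-space EEG from a three-task
working-memory session (delayed match-to-sample plus 1-back and 2-back),
with the four statistical structures the analyses target:

- *Aperiodic background*: per trial and channel, Gaussian noise with power
  spectral density ∝ 1/f^χ, synthesised by spectral shaping of white noise
  with random phases and an analytic variance normalisation (default
  χ = 1, RMS 10 µV — a typical broadband EEG scale).
- *Frontal theta oscillators*: a sinusoid added on a fronto-medial channel
  set during delay epochs, with per-trial frequency drawn from
  Normal(mean, 0.4 Hz) truncated to ±1 Hz and uniform phase. Condition
  means are 5.85 Hz (1-back), 5.77 Hz (2-back) and 6.0 Hz (DMS); a second
  preset pair (6.05 / 5.99 Hz) defines the scenario analysed after IRASA
  1/f removal. The per-trial frequency jitter is essential: the condition
  means sit off the 0.2 Hz analysis grid and only the across-trial average
  can converge to them.
- *Category patterns*: one fixed random spatial vector per class (drawn
  once per session), added as a constant offset on posterior channels
  during stimulus and delay epochs. Default strength 8 µV distributed over
  the unit-norm pattern.
- *Fz–posterior coupling*: a common band-limited (4–8 Hz) Gaussian signal
  mixed into the seed and target channels with weight `strength`, plus
  independent band noise with weight `1 − strength` (defaults 0.6 for
  n-back, 0.15 for DMS).

Session structure follows the task design: 12 n-back blocks (8 × 2-back,
4 × 1-back) of 36 + n trials each, two DMS runs of 90 trials (15 exemplars
× 6 presentations), 10 s inter-block baselines before and after every
n-back block, and per-trial duration jitter of {0, 50, 100, 150} ms
balanced within block (counts differ by at most one when the block length
is not a multiple of four). Epoch arrays are rectangular at the minimum
epoch duration with 200 ms of pre-onset padding stored, so per-epoch
baseline correction needs no cross-epoch stitching; the jitter lives in
the metadata. Because epoch types differ in duration, a session is
returned as one `EpochSet` per task × epoch type.

**Free parameters.** The oscillator amplitude (4 µV against the 10 µV
background; DMS at one third of that), the pattern strength and the
coupling strengths are not dictated by the underlying design, which
reports only the recovered statistics; they were fixed once at values
giving a delay-period band SNR comfortably above 2, and all tests run at
those defaults. The default sampling rate is 256 Hz — sufficient for all
sub-10 Hz analyses — and the default desk-scale montage is a synthetic
64-channel Fibonacci layout on the upper unit hemisphere with `Fz` and
`Pz` anchored at their canonical positions (any channel count ≥ 8 works).

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: ocular/muscle artifacts,
volume-conduction mixing (injected effects have hard channel boundaries,
real topographies do not), non-stationary oscillatory bursts, cross-trial
autocorrelation, and behavioural–neural coupling. Recovery rates here are
upper bounds on what identical analyses achieve on real data.

## Spectral estimation

Time-resolved power uses a sliding Hanning-tapered Fourier transform with
frequency-dependent window length (2 cycles below 4 Hz, 3 at 4–4.5 Hz, 4
at 5–5.5 Hz, 5 from 6 Hz) in 50 ms steps; coefficients are normalised so a
unit-amplitude sinusoid yields power 1 at its bin, and window positions
that would exceed the epoch are NaN. Whole-epoch spectra for the peak
statistic use a single Hanning taper zero-padded to `rate / grid_step`
samples (0.2 Hz grid ⇒ 5 s equivalent at integer rates); when an epoch
exceeds that length the FFT length is raised to a multiple and the
requested grid subselected, so the grid step is exact in every case.

**Peak statistic.** Local maxima are strict interior maxima; prominence is
height above the higher of the two flanking bases with the band edges
acting as bases (the standard MATLAB/scipy convention); ties resolve to
the lower frequency; a trial with no interior maximum is discarded (a
value, not an error — discarded fractions are reported and stay below 1 %
at default SNR). Spectra are averaged over the frontal channel set
*before* peak detection.

**IRASA.** For each resampling factor h ∈ {1.10, 1.15, …, 1.90} the signal
is resampled up by h and down by 1/h (Fourier resampling) and both
spectra are read out at the original sampling rate, moving any narrowband
peak to f/h and f·h while the scale-free component is invariant under the
geometric mean of the pair; the fractal spectrum is the median across
factors and the oscillatory residual is the original minus the fractal
(negative off-peak values are expected and retained). IRASA is applied
per trial, matching the per-trial peak pipeline; a condition-average
application is available through the same function.

*Bias correction.* A single-taper power estimate is exponentially
distributed about the true PSD (χ², 2 dof). The geometric mean of the two
independent resampled estimates is then PSD·√(E₁E₂) with Eᵢ ~ Exp(1),
whose density is 4x·K₀(2x), and the median across the factor set
underestimates the PSD by the expected sample median of that variable
(≈ 0.643 for 17 factors, computed by order-statistic quadrature). The
fractal estimate is divided by this constant; without it the residual on
pure 1/f input is biased upward by ~45 % of the fractal power, with it
the trial-averaged residual is below 10 %. The constant is model-derived,
cached per factor count, and independent of the data.

## Statistics

**Cluster-based permutation test.** Per-bin paired *t*; two-tailed
cluster-forming threshold at α = 0.05; suprathreshold bins of equal sign
clustered over the channel neighbour graph × frequency/time lattice;
clusters spanning fewer than 3 distinct channels discarded ("spanning
extent" reading; the per-bin neighbour-count reading is available as
`mode='neighbour'`); null distribution = per-tail maximum surviving
cluster mass over 500 random per-unit condition flips; p-values use the
add-one estimator (never exactly 0) and each tail is tested at α/2.
Empirical family-wise error on pure-noise simulations is ~0.05 (600
replicates during development; the acceptance suite re-checks 200).

**Holm correction** is step-down with a running maximum and deliberately
*uncapped* — adjusted values slightly above 1 are reported as computed
(a `cap=True` option restores the conventional behaviour).

**Repeated-measures ANOVA** (two within factors) delegates to pingouin
with no sphericity correction by default (Greenhouse–Geisser optional);
an independently coded sums-of-squares oracle guards it in the tests.
**Power** of the paired *t* comes from the noncentral *t* distribution
(statsmodels): n = 28 gives 0.801 at d = 0.55, α = 0.05. **Outliers**
follow the 1.5 × IQR rule with linear-interpolation quartiles.

## Decoding

The LDA is fitted in batch across time points: per class, the empirical
covariance is shrunk toward a scaled identity with the Ledoit–Wolf
coefficient computed in standardised feature space (matching
scikit-learn's `solver='lsqr', shrinkage='auto'` to machine precision —
unit-tested), classes weighted by their priors, and the discriminant
solved jointly for all time points. When features outnumber trials (the
searchlight case: channels × window samples) the shrunk covariance has the
form diag(d) + UᵀU and the solve goes through the Woodbury identity in
sample space — numerically identical, ~100× faster. Folds are stratified
and reshuffled per repeat with seeds derived from the master seed;
accuracy is averaged over folds, then repeats. The pipeline order is
fixed: resample to 200 Hz → 100 ms sliding average → baseline-correct to
the preceding 200 ms → exemplar pair-averaging (random pairs, odd trial
passes through) → decode.

Temporal generalization shares fold assignments with the plain time
course, so the matrix diagonal reproduces it exactly. Group significance
clusters adjacent above-chance time points with a sign-flip max-sum null;
only positive (above-chance) clusters define decoding windows.

## Coherence

Cross-spectral densities come from the tapered coefficients of the same
time-frequency decomposition (theta grid 4–8 Hz, 0.5 Hz). Coherence is
computed per frequency × time and then averaged over the window of
interest (trial-averaging before time-averaging; the pooled-time variant
is an option). Magnitude-squared coherence is biased upward at low trial
counts (≈ 1/N under independence — verified against that analytic value),
so condition contrasts subsample the larger condition (10 draws without
replacement, maps averaged) to the smaller condition's trial count. The
inter-block baseline is never used as a coherence comparator. Contrasts
cluster jointly over channels × frequencies.

## Problem sizes

The validation suite runs cohorts of 28 simulated participants (40 trials
per condition for the peak analyses; 20 per condition for the channel-level
injection recoveries at 16 channels, 256 Hz), 20 replicate cohorts for the
slowing-detection rate, 20 permutation seeds for the chance-level decoding
control, and 200 pure-noise datasets (12 units, 16 channels × 9
frequencies, 200 permutations) for the type-I calibration — sizes chosen
as the smallest at which the targeted effects and error rates are stable
across seeds.

## Known limitations

- The cluster test assumes exchangeable units under the null (within-
  subject designs only); between-subject designs are out of scope.
- The IRASA bias correction is derived for single-taper (2 dof) spectra;
  applying `irasa` to pre-averaged data would over-correct. Residual
  correlation between resampling factors makes the constant slightly
  approximate (the pure-1/f residual is ~6 %, not 0).
- Decoding is strictly two-class; multiclass designs would need
  one-against-one reduction.
- Coherence is undirected; no phase-lag or causality measures are
  provided.
- `EpochSet` holds data densely in memory; a 128-channel, 1024 Hz session
  fits but is wasteful — desk-scale parameters (≤ 64 channels, 256 Hz) are
  the intended regime.
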