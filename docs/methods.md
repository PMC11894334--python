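# Methods

## Signal model and ground truth

Synthetic EEG channels are Ornstein–Uhlenbeck (OU) processes, simulated
exactly as AR(1) with coefficient `phi = exp(-1/(fs * tau))` and
stationary unit variance, scaled to 20 µV RMS, plus white measurement
noise at 20 dB SNR.  The OU autocorrelation is `exp(-lag/tau)`, so the
continuous-limit ACW-50 is `tau * ln 2` — a closed-form oracle for every
timescale estimator in the package.  An OU-plus-noise model was chosen
over 1/f synthesis precisely because it admits this analytic ground
truth; the cost is that synthetic spectra lack the power-law background
and oscillatory peaks of real EEG (see *Limitations*).

The per-channel timescale map is
`tau(ch, subject) = tau_background * ch_factor * subject_factor`, with
lognormal channel heterogeneity (log-SD 0.10, a fixed scalp map per
cohort) and lognormal subject scaling (log-SD 0.10).  Patients receive an
additive `tau_effect` (default +50 ms on a 50 ms background) on a chosen
electrode patch during the interoception condition only, mimicking a
spatially localised slowing.  Recordings last two 2-minute blocks per
condition at 256 Hz on a Biosemi-style 128-channel unit-sphere montage
(evenly subsampled for smaller test caps).

ECG: RR intervals are i.i.d. Gaussian (mean `60/mean_hr`, SD `sdnn`,
truncated below at 0.3 s); defaults 70 bpm and 50 ms SDNN are typical
resting values for elderly cohorts.  The waveform is a Gaussian-bump
PQRST template train (R amplitude 1 mV) plus 0.25 Hz baseline wander and
white noise.  No autonomic spectral structure (RSA, Mayer waves) is
modelled: SDNN is the only HRV quantity consumed downstream.  Taps are
beats plus a 200 ms motor latency (a plausible simple-reaction delay,
configurable), Gaussian jitter, and Bernoulli misses.

Behavioural scores are Gaussian with group-specific means — healthy
control reference values (MMSE 28.0 ± 1.2, IFS 22.5 ± 3.5, Mini-SEA
emotion 12.0 ± 1.5, faux pas 13.0 ± 1.9) minus configurable patient
deficits — clipped to each scale's range, with MCAR missingness on
cognitive cells.  Demographics are balanced across groups by
construction, with sex and site assignment patterns de-phased so the
design stays full rank at any n.

### Scalar ACW-map generator

`simulate_acw_maps` draws per-subject ACW-50 maps directly from the
ground-truth model (`tau * ln 2` times lognormal factors) for
large-replicate calibration studies where re-estimating full EEG for
hundreds of cohorts would be wasteful.  Its noise model has three parts:
a global subject factor (log-SD 0.1), a spatially smooth per-subject
field (log-SD 0.2, squared-exponential covariance over great-circle
distance, length-scale 0.5 rad), and independent electrode noise (log-SD
0.05).  The smooth field is the scalar-map analogue of volume
conduction; without cross-electrode correlation a 64-electrode null map
almost never produces a ≥ 5-electrode supra-threshold component, and the
"any significant cluster" rate collapses far below its nominal level, so
correlation is essential for a meaningful calibration study.

## ACW estimation

The ACF is the biased (normalise-by-N) sample autocorrelation on a
1-sample lag grid, computed via FFT; ACW-50 is the first lag strictly
below 0.5, at sample resolution with no sub-sample interpolation (the lag
grid *is* the method's resolution).  Epochs whose ACF never reaches 0.5
are flagged missing, never censored at the maximum lag — censoring would
bias slow channels downward.

**Mean removal.**  For heartbeat-locked epochs the subtracted mean is the
channel's *recording-level* mean, not the 3-s epoch mean.  A 3-s window
spans only ~15 timescales of a slow (`tau` ≈ 0.2 s) channel, and
demeaning within the window shrinks its ACF by roughly `2*tau*fs/N`,
biasing the ACW-50 of slow channels down by up to a third.  The
band-passed signal is zero-mean to begin with, so recording-level
demeaning costs nothing for fast channels; measured recovery is within
±14% across `tau` in [0.02, 0.2] s (the residual +13% at `tau` = 0.02 s
is the sample-resolution ceiling effect of the first-crossing rule).
Standalone `acf()` on a single segment still subtracts the segment mean.

Epochs crossing task-block boundaries are excluded by default (blocks are
separate recordings in the task); both pooled-block and per-block
policies are supported, pooled being the default.  Only the broadband
0.5–30 Hz signal is analysed; per-band ACW is out of scope.

## Preprocessing

Band-pass: 4th-order Butterworth, applied forward–backward (zero phase),
then polyphase anti-aliased resampling to 256 Hz.  Reflection padding is
extended to ~6 periods of the high-pass corner; the default few-sample
padding leaves multi-second 0.5 Hz edge transients.  Average reference
subtracts the instantaneous mean of non-excluded (scalp) channels;
non-EEG channels are excluded by default and passed through.  Bad-channel
repair is inverse-great-circle-distance interpolation over the k = 8
nearest good electrodes (weights normalised to 1); bad-channel *labels*
are caller-provided — auto-detection is out of scope.  ICA artifact
correction is deliberately outside the computational core: the pipeline
accepts already-cleaned or synthetic data, and any external cleaning step
can be inserted between reading and ACW/HEP estimation.

R-peak detection is Pan–Tompkins: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds
(SPKI/NPKI updates), 200 ms refractory period, search-back for long
gaps, and refinement of each detection to the local maximum of the
polarity-corrected raw ECG within ±50 ms.  Quality flags: flat input or
no supra-threshold candidates → empty train; median RR < 0.3 s or a
75th/25th-percentile candidate-peak-height ratio < 5 (structureless
noise) → `quality_ok = False` with a warning.

## Cluster statistics

Per electrode, a two-sided Mann–Whitney rank-sum test with average ranks
for ties: exact by full enumeration of all `C(n, nA)` assignments when
the pooled n ≤ 12, otherwise the tie-corrected normal approximation with
continuity correction.  Cluster formation thresholds at p < 0.025,
connects supra-threshold electrodes of the same difference sign through
the montage adjacency graph (neighbours = great-circle distance below a
radius auto-tuned to a mean degree of 5–9), and discards components with
fewer than 5 electrodes.  A cluster's mass is the sum of its standardized
statistics.  Significance comes from a max-|mass| permutation null:
group labels are reassigned (sizes preserved) `n_perm` times, the whole
pipeline re-runs on each relabelling, and
`p = (1 + #{null >= |mass|}) / (1 + n_perm)`.  Because pooled ranks are
invariant under relabelling, all permutation rank sums come from a single
matrix product, and the exact small-n null is enumerated once and reused
for every relabelling.  Clustering is spatial (one epoch-averaged scalar
per electrode), not spatio-temporal.

## Heartbeat-evoked potentials

Epochs span −300..600 ms around each R-peak.  Low drifts are removed by
a linear trend fitted on the *continuous* per-channel signal: a line
fitted inside the 900 ms epoch would absorb roughly half of a sustained
200–500 ms deflection (verified analytically and numerically with an
injected 10 µV boxcar, which recovers at 5.06 µV under per-epoch
detrending and 10.00 µV under continuous detrending).  Each epoch is then
baseline-corrected to the mean of −300..0 ms.  Trial rejection z-scores,
across trials and per channel, (a) each trial's mean log-probability
under the pooled amplitude histogram (Freedman–Diaconis bins) and (b)
each trial's sample kurtosis; a trial is rejected when |z| > 2.5 on
either measure on any channel, in a single pass.  Zero-variance measures
are kept (z undefined → no rejection).  Because the rule is OR-across-
measures and max-across-channels, its family-wise null rejection rate
grows with channel count; with 4-channel epoch sets the Gaussian-null
rate is ~10–15%.  The HEP scalar is the mean baseline-corrected voltage
over kept epochs, a configurable electrode set (default: all; in the
pipeline, the significant ACW-cluster electrodes would be the natural
ROI) and 200–500 ms.

## Behavioural metrics and inference

The mean distance index (MDI) is the nearest-heartbeat distance of each
tap normalised by the local inter-beat interval, averaged over taps
(0 = perfect entrainment, 0.5 = taps midway between beats).  The
definition is isolated behind one function so an alternative convention
can be swapped in; tests rely only on its calibration (half-normal mean
under Gaussian jitter) and monotonicity.  HRV is the mean and population
SD (SDNN) of successive R-peak differences, in ms.  Group description
tables use Welch's unequal-variance t (which reproduces the reference
cohort's printed demographic statistics from printed summaries) and
Pearson chi-square without continuity correction for sex ratios.

Regression models predict a behavioural outcome from dummy-coded
diagnosis (control = 0, patient = 1; analogously sex and site), the
cluster-mean ACW-50, age, sex, education and site — optionally plus the
HEP scalar.
Missing cells are filled by scikit-learn's IterativeImputer with a
BayesianRidge estimator (chained equations, initialised at column means);
predictors are dummy-coded *before* imputation so categorical predictors
inform the imputation model.  Observed cells are never altered.
Per-predictor p-values are Benjamini–Hochberg FDR-corrected within each
model, excluding the intercept (whose p is reported uncorrected).  Every
model also reports case-resampling bootstrap coefficients, SDs and
percentile 95% CIs (B = 5000 by default; singular resamples are redrawn
and counted, with an error above 10%).  Percentile rather than BCa
intervals are used — plain bootstrapped 95% CIs are the convention this
layer mirrors.

## Numerical and design choices

- Seeds: every stochastic component takes an explicit seed; cohort
  generators derive per-subject/per-stream generators from
  `SeedSequence([seed, stream...])`, and the pipeline derives per-stage
  seeds from a master seed, so reruns are bit-identical.
- On-disk formats: recordings are written as FIF (MNE-native) with
  events/montage as TSV, behaviour as CSV and ground truth/provenance as
  JSON; readers also accept EDF and BDF.
- Degenerate inputs: zero-variance ACF segments, all-rejected trial
  sets, all-missing columns, rank-deficient designs (reported with the
  most collinear column pair), zero-margin tables and non-monotone event
  trains all raise typed `ConfigError`s rather than propagating NaNs.
- Problem sizes in the test and acceptance studies (e.g. 2 × 120 s
  recordings for timescale recovery, ~280 heartbeat epochs per estimate,
  200 null cohorts / 50 effect cohorts at 500 permutations for cluster
  calibration, 300 simulated regressions at B = 500, 400 cohorts for
  effect recovery) were sized to keep each study's Monte-Carlo error
  well inside the tolerance it checks.

## Limitations

- The OU generator has no 1/f background, oscillatory peaks, cardiac
  field artifact, eye/EMG artifacts, or volume-conducted channel mixing
  (the full-EEG generator's channels are independent given the tau map);
  passing tests demonstrate estimator correctness under the stated
  model, not robustness to real-EEG nuisance structure.  Spatial
  correlation is modelled only at the scalar-map level.
- The RR model is i.i.d. Gaussian; metrics beyond mean RR and SDNN
  (frequency-domain HRV, RSA) would need a richer generator.
- Imputation is single (not multiple), so downstream SEs slightly
  understate imputation uncertainty — consistent with the convention
  this package mirrors, and visible in recovery studies only at the
  percent level.
- Time-resolved (electrode × time) clustering and threshold-free cluster
  enhancement are out of scope; the cluster layer operates on one scalar
  per electrode.
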