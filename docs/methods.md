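# Methods

This note documents the models, numerical choices and design decisions
behind `hurstlab`, and what the synthetic-data studies do and do not show
about real gait data.

## The Hurst–Kolmogorov process and fGn simulation

All simulated series are fractional Gaussian noise (fGn): the stationary
Gaussian process with autocorrelation

    ρ_k = ½|k+1|^{2H} + ½|k−1|^{2H} − |k|^{2H},   k = 0, 1, …

H = 0.5 is white noise; H ∈ (0.5, 1) persistent; H ∈ (0, 0.5)
anti-persistent. Simulation uses circulant embedding (Davies–Harte): the
(2N)-point circulant extension of the autocovariance is diagonalized by the
FFT, Hermitian-symmetric Gaussian spectral weights are drawn, and the
inverse transform yields a series whose covariance equals the target
exactly (no truncation or AR approximation). For fGn the embedding
eigenvalues are nonnegative in practice; a Cholesky-of-Toeplitz fallback
covers the contractual failure case. Batched generation computes per-series
autocorrelation rows and FFTs in one vectorized sweep.

Correctness is tested with the unbiased cross-replicate product moment
E[x_t x_{t+k}] (the process mean 0 and variance 1 are known), not the
time-averaged sample ACF: for long-memory series at a few hundred points
the mean-centered sample ACF is biased low by an amount far exceeding
Monte-Carlo error, and would mask (or fake) generator defects.

Series are generated with mean 0 and SD 1. Both estimators are affine
invariant (tested to 1e−10 / 1e−9), so the scale is a free choice; the
cohort generator maps each gait variable onto a plausible native scale
(e.g. stride interval 1.10 ± 0.035 s) purely for realism of the files.

## DFA

The series is mean-centered and integrated; the profile is split into
non-overlapping windows of size n anchored at the series start (trailing
remainder discarded); a first-degree OLS trend is removed per window; F(n)
is the RMS residual over all retained points; α is the unweighted OLS slope
of log F(n) on log n.

Choices: **all integer scales in [4, floor(N/4)]** (for N ≤ 200 the integer
grid is small and maximizes fit points — reference implementations often
use log-spaced subsets, which have fewer points and therefore noisier
slopes; see "Known limitations"); **linear detrending only**; **no backward
pass**. Scales with F(n) = 0 (possible only for degenerate inputs) are
excluded from the fit and flagged; fewer than three positive scales is an
error. Mean-centering before integration is what makes α shift-invariant.

## HKp

For a stationary Gaussian HK process with unknown mean and variance under a
noninformative prior, integrating out both nuisance parameters leaves the
marginal posterior over H alone:

    log f(H | x) = −½ log|R| − ½ log(1ᵀR⁻¹1)
                   − (n−1)/2 · log( xᵀR⁻¹x − (1ᵀR⁻¹x)² / (1ᵀR⁻¹1) )

with R the n×n Toeplitz correlation matrix at H. All evaluation is in log
space via Cholesky factorization (jitter 1e−10·I on failure). The estimator:

1. **Peak**: 51-point scan brackets the mode, bounded Brent refines to
   1e−6 in H; a dense 999-point scan is the fallback. The posterior is
   unimodal on every series we have examined; the scan guards the optimizer
   against a hypothetical local trap.
2. **Accept–reject**: draw H_cand ~ U(0,1) and u ~ U(0,1); accept when
   u ≤ exp(log f(H_cand) − log f_peak) (clamped to [0,1]); iterate to 50
   accepted values; the **median** is the point estimate. Underflowing
   candidates are rejected; a hard cap of 10⁶ candidate draws signals a
   pathological density.

**Grid mode** (simulation-scale): a per-length cache of Cholesky factors on
an H grid (step 0.005 over [0.005, 0.995]) evaluates the posterior of an
entire batch of same-length series as one triangular solve per grid point
(BLAS-3), after which accept–reject runs fully vectorized with linear
interpolation of the log density between nodes. Linear interpolation never
exceeds the node maximum, so acceptance ratios stay in [0, 1]. Contract,
enforced by tests: grid densities match exact densities at the nodes to
1e−8, the grid peak is within one grid step of the exact peak, and
matched-stream point estimates agree within 0.02. Grid mode is used by the
power and reliability drivers; single-series estimates default to exact
mode.

## Reliability: ICC(3,k)

Days are the repeated measurements: per-trial H estimates from trials 1..k
of each day are averaged (the same k trials on both days, in acquisition
order), and the subjects × 2 table feeds a two-way mixed-effects
consistency ICC, ICC(3,k) = (BMS − EMS)/BMS, with the Shrout–Fleiss
F-bounds as the 95% CI. Bands: poor < 0.5 ≤ moderate < 0.75 ≤ good <
0.9 ≤ excellent — boundary values take the upper band. Stride slices are
taken from the **end** of each trial (familiarization effects concentrate
at trial onset). Zero between-subject variance is a signaled error, not a
NaN; an error sum of squares below 1e−12 of the total (an exact repeat up
to rounding, e.g. day 2 = day 1 + constant) reports ICC = 1 exactly.

Grid cells share per-trial estimates across k within a stride count, so a
full 9-row column costs one estimation sweep. Failed cells are flagged
(`band="failed"`), never dropped.

## Power and minimum sample size

Design: group A mean true H 0.75, group B 0.75 + ΔH; per-subject trial-level
true H compound-symmetric with ICC 0.65 and marginal SD 0.11; one fGn
realization per trial; H estimated per trial and averaged within subject;
two-sided Welch t-test at α = 0.05 on the subject means. (Welch vs Student
is immaterial at equal n and equal design SD; the choice is a switch.)
Power = rejection proportion, with a Clopper–Pearson 95% CI. The minimum-n
search simulates the largest grid n once per replicate and reuses its first
subjects for every smaller n (common random numbers), which suppresses
Monte-Carlo jitter between adjacent grid points.

**Support handling for sampled true H.** Draws with mean 0.83–0.87 and SD
0.11 place 4–12% of mass at or above 1, outside the fGn support. The
default is to **clip** to [0.001, 0.999]: clipping shifts the realized group
mean by at most ~0.003, so the realized between-group difference stays at
its nominal ΔH — the property the power design depends on. Rejection
resampling (available as `truncate="resample"`) preserves Gaussian shape
inside the support but drags the upper group's mean down by 0.014–0.025,
attenuating ΔH by 8–20% and inflating every minimum-n by 15–40%; we treat
the nominal ΔH as the design quantity and accept the small pile-up of
probability at the boundary instead.

Replicates with a failed (non-finite) estimate are regenerated under the
next attempt sub-seed and counted; with the default estimators this path is
essentially never taken.

**Seeding.** A single master seed expands into independent child streams
via `numpy.random.SeedSequence` spawn keys per (purpose, replicate,
attempt), so any condition or replicate is reproducible in isolation and
results do not depend on execution order. Identical configuration + seed
reproduces outputs exactly (byte-identical CSVs where files are written).

## Synthetic cohort generator

True H follows a variance-components model per subject: group mean +
subject effect + subject×day effect + subject×day×trial effect, each
zero-mean normal with configurable SD (defaults 0.11 / 0.03 / 0.05; group
means default to 0.75, the anchor of the power design and a typical
stride-interval persistence level). A subject whose 2×9 true-H block leaves
(0, 1) is redrawn whole. `day_sd_for_target_icc` inverts the population
ICC(3,2) of k-trial day averages, σ_s² / (σ_s² + σ_v²/2) with
σ_v² = σ_day² + σ_trial²/k, so cohorts can be designed to a target
reliability and the pipeline validated against it.

What the generator emulates: the cohort's dimensional structure (groups,
2 days, 9 trials, ≥ 50 strides), stationary persistent stride dynamics with
subject/day/trial heterogeneity in H, and variables on native scales. What
it does not emulate: nonstationarity and drift, gait-event detection error,
inter-variable coupling within a stride, non-Gaussian tails, or any aging
effects beyond group-mean H. Passing reliability/power tests therefore
validates the **estimators and the statistical pipeline**, not claims about
any particular empirical dataset; the empirical reliability surfaces
require the original data and are out of scope.

## Problem sizes used in the shipped studies

The acceptance studies run at desk scale by design: minimum-n searches use
300 common-random-number replicates per grid point (the original design
point is 1000 independent replicates; `reps` is a parameter), null
calibration uses 2000 replicates, and the white-noise DFA check uses 100
series of length 1000. At 300 replicates the binomial SE of a power
estimate near 0.8 is ±0.023, i.e. one to two grid steps of jitter in a
minimum-n readout.

## Known limitations

- DFA with the full integer scale grid is *more* statistically efficient
  than log-spaced-scale implementations; published minimum-n values derived
  from a noisier DFA will exceed ours at short lengths (we measure
  SD(α) ≈ 0.18 at N = 50 vs ≈ 0.235 implied by the comparison values).
  The scale set is the documented, configurable choice.
- The HKp posterior assumes a stationary Gaussian HK process; on strongly
  nonstationary input (α > 1 regime) the posterior piles up near H = 1 and
  the estimate saturates rather than diagnosing nonstationarity.
- ICC confidence intervals use the standard F-approximation; for n < 5
  subjects they are wide and fragile, and the grid flags rather than hides
  degenerate cells.
- Grid-mode HKp supports series up to length 1024 (cache memory grows as
  G·N²); longer series should use exact mode.
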