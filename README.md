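# hurstlab

Hurst-exponent estimation and study-design tools for **short, stationary
gait time series** — stride intervals, stride lengths, joint ranges of
motion — where classical long-range-correlation analysis runs out of data.

Stride-to-stride fluctuations in healthy walking are persistent: the Hurst
exponent H of the stride-interval series typically sits above 0.5, and
departures from that persistence carry clinical meaning. Estimating H from
a four-minute walking trial (≈ 50–200 strides) is hard: the standard
estimator, Detrended Fluctuation Analysis (DFA), is noisy at these lengths,
which degrades test–retest reliability and inflates the sample sizes needed
to detect group differences. `hurstlab` implements both DFA and a Bayesian
Hurst–Kolmogorov estimator (HKp) that is markedly more precise on short
series, plus the machinery to quantify exactly how much that precision buys
in reliability and statistical power.

## What's inside

- **`hurstlab.fgn`** — exact fractional Gaussian noise simulation
  (circulant embedding) with the Hurst–Kolmogorov autocorrelation
  ρ_k = ½|k+1|^{2H} + ½|k−1|^{2H} − |k|^{2H}; correlated trial-level
  true-H sampling (compound symmetry via Cholesky); a synthetic multi-group,
  two-day, nine-trial gait-cohort generator.
- **`hurstlab.dfa`** — DFA with linear detrending over every integer window
  size in [4, N/4]; α is the OLS slope of log F(n) on log n (α = H for
  stationary series).
- **`hurstlab.hkp`** — the Bayesian estimator: marginal posterior of H for
  a stationary Gaussian HK process with mean and variance integrated out,
  peak found by bounded optimization, accept–reject sampling until 50 draws,
  median as the point estimate. A grid-cached batch mode makes
  simulation-scale use practical.
- **`hurstlab.reliability`** — between-day ICC(3,k) (two-way mixed-effects,
  consistency) grids over stride counts × trials averaged, with
  Shrout–Fleiss confidence intervals and the poor/moderate/good/excellent
  bands.
- **`hurstlab.power`** — Monte-Carlo power for a two-group Welch-t design on
  mean H, and minimum-sample-size search with common random numbers.
- **`hurstlab.io` / `hurstlab.cli`** — long-format CSV interchange and the
  `hurstlab` command-line tool (`simulate-fgn`, `generate-cohort`,
  `estimate`, `reliability`, `power`, `min-n`).

## Worked example

Estimate H for one simulated persistent series (true H = 0.8, 128 strides):

```python
from hurstlab import simulate_fgn, dfa_estimate, hkp_estimate

series = simulate_fgn(0.8, 128, seed=42)

d = dfa_estimate(series)
print(d.point, d.diagnostics.r_squared)   # 0.920  0.929

h = hkp_estimate(series, seed=0)
print(h.point, h.diagnostics.peak_h)      # 0.776  0.753
```

DFA overshoots this particular short series (α = 0.92, a typical size of
its sampling error at N = 128), while the HKp point estimate — the median
of 50 accept–reject draws from the posterior — lands at 0.776 with the
posterior mode at 0.753.

How many participants per group does a study need to detect a 0.08
difference in mean H with two 150-stride trials per subject, estimating by
HKp (within-group SD 0.11, between-trial ICC 0.65, Welch t-test, α = 0.05)?

```python
from hurstlab import PowerCondition, min_n_for_power

cond = PowerCondition(delta_h=0.08, n_trials=2, series_length=150, method="hkp")
res = min_n_for_power(cond, range(24, 45, 2), reps=300, seed=1)
print(res)                 # 30
print(res.powers.head(4))  # n=24: 0.700, 26: 0.737, 28: 0.790, 30: 0.810
```

At 300 replicates per grid point the estimated power crosses 0.80 at n = 30
per group (the binomial jitter at this replication count is a couple of
grid steps; 1000 replicates tightens it). The same search with
`method="dfa"` needs roughly twice the participants — the practical case
for the Bayesian estimator on short trials.

From the shell:

```sh
hurstlab min-n --delta-h 0.08 --trials 2 --length 150 --method hkp \
    --n 24:44:2 --reps 300 --seed 1 --out minn.csv
```

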