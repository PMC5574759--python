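# Methods

This document describes the models implemented in `tropichron`, the default
parameter values and why they were chosen, what the synthetic generator does
and does not emulate, the numerical choices, and known limitations.

## 1. Synthetic data generator

### Ring widths

Tree *i*, radius *j*, cambial age *a*, calendar year *t*:

```
w = (A·exp(−k·a) + c) · exp(beta·z_t + e_ij),   e_ij ~ N(0, sigma_ring²)
```

- `age_trend = (A, k, c) = (3.0, 0.03, 0.4)` mm — a negative-exponential
  juvenile trend typical of open-grown tropical trees, levelling at ~0.4 mm.
- `z_t` is the standardized log of the Oct–Dec (OND) mean of the simulated
  streamflow series, so the climate signal is shared by all trees.
- `beta = 0.55`, `sigma_ring = 0.35`. These were calibrated, before the test
  suite was frozen, so the *climate signal alone* sustains a mean
  inter-series correlation near 0.6 and crossdating pass fractions of
  0.93–0.99 — the common signal must not depend on shared ring errors, or
  removing the errors would also remove the chronology quality.

### Dating errors (the point of the exercise)

Two error modes, both drawn at the *population* level (event years shared by
all trees, `participation = 1.0` by default) because a climatic trigger —
e.g. a mid-season dry spell — affects the whole stand. Per-tree independent
errors would destroy crossdating; shared errors are exactly the pathology
that crossdating cannot detect.

- `p_extra = 0.3` per year within `extra_era = (1830, 1985)`: the tree forms
  an intra-annual band that is counted as a ring (inserts one ring; dendro
  dates pith-side of it become too old).
- `p_merge = 0.02`: a formed ring is not recognised (removes one ring;
  partially cancels extras).
- `p_missing = 0.02` per radius: the ring is locally absent on that radius
  only (a within-tree measurement nuisance, not a dating error at tree
  level).

The era bound 1985 means ring counts are correct over 1986–2006 and drift
with roughly 0.28 net surplus rings/yr earlier — producing multi-year
dendro-vs-¹⁴C offsets at depth while the recent decades stay aligned.

- Defaults `n_trees = 15`, two radii per tree plus one extra radius on one
  tree (31 series), `span = (1830, 2006)`, staggered recruitment over
  `recruit_span = 40` years.

### Climate, fields and indices

Monthly precipitation/temperature/streamflow follow fixed seasonal cycles
with AR(1) (φ = 0.5) interannual anomalies; streamflow is lognormal
(SD 0.25) and carries the common forcing; an ENSO-like index couples to it
with correlation −0.6. Gridded fields place the forcing in a rectangular
signal box (`effect = 0.8`) on an otherwise independent grid.

### Bomb curve and ¹⁴C measurements

The stylized Northern-Hemisphere Fm curve: plateau 0.980 up to 1954, linear
rise to a 1.830 peak at 1964, fast linear decline at 0.026 Fm/yr to 1.050 at
1994, then a slow tail to 1.040 at 2006 (record 1900–2008); constant curve
SD 0.006. The fast-decline slope is chosen so that, at the default
measurement SD `meas_sd_fm = 0.003`, the nearest-neighbour-year confusion
probability on the decay limb is ~1.5 × 10⁻⁵ per sample — single-ring
calendar dating there is essentially exact, as with the real atmospheric
record's steep post-peak decline. Measurements are the curve value at the
ring's *true* year plus N(0, meas_sd²) noise; extra rings split one year's
wood, so both share that year's Fm.

### What the generator does *not* emulate

Wood anatomy and sample preparation; laboratory chemistry; real calibration
datasets; spatially correlated climate noise; ring-width dependence on age
beyond the deterministic trend; non-stationary climate sensitivity; false
rings that are anatomically distinguishable (all simulated extras are
counted as rings by construction).

## 2. Chronology construction

- **Detrending**: discrete cubic smoothing spline, i.e. Whittaker–Henderson
  penalized least squares with a second-difference penalty. The amplitude
  transfer is analytically `H(ω) = 1/(1 + λ(2 − 2cos ω)²)`; λ is solved in
  closed form so that `H = 0.5` at a 60-year wavelength (the conventional
  "67%n / 50% cutoff" style choice, fixed here at 60 yr). Index = width /
  curve (ratio detrending).
- **Prewhitening**: AR(p) with p selected by AIC (max order 3 by default via
  `ar_select_order`); residuals are recentered to the series mean and the
  first p years dropped.
- **Chronology**: Tukey biweight robust mean (c = 9, MAD scale), minimum
  sample depth 2.
- **Signal strength**: r̄ = mean pairwise Pearson correlation over ≥20-yr
  overlaps; `EPS = n·r̄ / (n·r̄ + (1 − r̄))` with n = number of *trees*;
  running EPS in 50-yr windows stepped by 25 yr, onset = first window from
  which EPS stays ≥ 0.85.
- **Crossdating**: 20-yr segments lagged by 10 yr, each segment correlated
  with the biweight master of the other series; a segment fails when r falls
  below the one-tailed 99% critical value (`r_crit ≈ 0.52` at n = 20); for
  each segment the lag in ±10 yr maximising r is reported — a consistent
  best lag of −1 means the series is dated one year too young.

## 3. Climate response

- Screening: Shapiro–Wilk normality, Mann–Kendall trend, Pettitt
  change-point, each at α = 0.05; series shorter than 20 yr are refused.
- Bootstrapped Pearson correlations (pairs bootstrap, default 1000
  replicates, percentile CI at 95%, CI clipped to contain the point
  estimate); "significant" = CI excludes zero. Overlaps below 15 yr are
  refused, with the count in the refusal reason. Monthly, seasonal (OND
  default) and annual aggregations; gridded-field maps report per-cell r and
  a significance mask at p < 0.10.
- The pipeline's default response window is 1986–2006: within the synthetic
  design this is the era with no dating errors, so correlations measure the
  chronology's climate signal rather than its misalignment. Full-overlap
  correlations are computed alongside.

## 4. Stochastic response function (STM)

Observation `I_t = μ_t + α_t·X_t + ε_t` with state (μ, δ, α):

```
μ_t = μ_{t−1} + δ_{t−1}        (integrated random walk trend)
δ_t = δ_{t−1} + ζ_t,  ζ ~ N(0, σ²_ζ)
α_t = α_{t−1} + η_t,  η ~ N(0, σ²_η)
```

Kalman filter with diffuse initialization (prior variance 10⁷·var(I)),
prediction-error-decomposition likelihood, Nelder–Mead maximisation over
log-variances with multi-start (5 starts by default; ties broken toward the
smallest σ²_η, i.e. the most parsimonious time variation), then
fixed-interval (RTS) smoothing. Missing observations are skipped by the
filter. Pinning σ²_ζ = σ²_η = 0 collapses the model to the exact OLS
regression of I on X (verified to 1e-6 in tests). Explained variance is
`1 − var(I − μ̂ − α̂X)/var(I − μ̂)`, reported for both smoothed and filtered
states. A year is "significant" when zero lies strictly outside
α̂ ± 1.96·√var(α̂); the stability onset is the earliest year from which all
later years are significant.

The likelihood loop is numba-jitted when numba is importable (optional
`fast` extra) with an identical pure-NumPy fallback.

## 5. Radiocarbon validation

For each sample, candidate years are those with
`|Fm − curve(y)| ≤ 2·√(meas_sd² + curve_sd²)`, grouped into runs. A run that
touches the pre-bomb plateau is open-ended: the sample yields only a
latest-possible-year bound. A post-plateau run wider than 5 years (e.g. on
the flat post-1994 tail) is treated as uninformative and the sample is
excluded from offset statistics — pretending single-year precision there
would inject ±6-yr noise and could flip the verdict on error-free trees.

Within a tree, calendar years are assigned by dynamic programming over the
candidate sets under the constraint that years strictly increase with ring
position, minimising the total squared standardized Fm residual (maximum
likelihood), with total |dendro offset| as the tie-breaker only. Offsets are
`assigned − dendro` (positive = dendro dated too old); derived statistics
are the per-tree mean |offset|, excess rings per decade between consecutive
datable samples, and the cumulative ring-count mismatch.

## 6. Pipeline and verdict

Stages simulate → chronology → {climate, stm} → c14 → report; a failed stage
halts its dependents but not independent stages (c14 runs from the simulated
measurements even if chronology fails). Every stage logs input/output SHA
hashes; two runs with the same config are byte-identical.

The verdict is a pure function of stage outputs: if crossdating passes and
EPS ≥ 0.85 yet any tree's mean |offset| exceeds 1 year (the ±1-yr margin of
the bomb-pulse method), the flag is **"c14-refuted (despite passing dendro
QC)"**; with no tree over the margin it is **"consistent"**; with the c14
stage disabled it is **"not assessed"**.

## 7. Numerical choices

- Whittaker–Henderson solve via banded Cholesky (`scipy.linalg.solveh_banded`).
- Biweight mean iterated to 1e-10 with median/MAD initialization; zero MAD
  returns the median.
- All randomness flows from `numpy.random.default_rng` seeded from the
  config; per-purpose child seeds are derived deterministically so adding a
  stage never perturbs another stage's draws.
- RWL writing rounds to hundredths of mm half-up; the reserved stop value
  999 is nudged to 1000 (0.01 mm) with a warning rather than an error.
- Bootstrap CIs are percentile CIs; they are clipped to contain the point
  estimate to guard against degenerate resamples at small n.

## 8. Limitations

- The bomb curve is stylized, not a calibration dataset; absolute Fm values
  are representative of the Northern Hemisphere zone but not usable for real
  samples.
- EPS uses the standard r̄-based approximation; no variance-explained
  eigenvalue variant is implemented.
- The STM confidence bands are plug-in bands at the ML variance estimates;
  they do not propagate hyperparameter uncertainty, so their coverage is
  slightly anti-conservative in small samples (and, with a truly constant
  response, all years within a fit share essentially one estimate, making
  coverage statistics across time points highly correlated).
- Single-predictor STM only; no formal change-point tests.
- Crossdating reports lags but does not automatically re-date series.
- The ¹⁴C assignment assumes at most one sample per ring and monotone ring
  order; mixed or re-used wood is out of scope.
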