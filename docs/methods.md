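# Methods

## Model

Classical test theory: `x_j = t_j + e_j` with `cov(t, e) = 0`, reliability
`r_xx = s_t²/s_x²`, all scores reported on a norm scale `(M, s_x)` (default
T scale: M = 50, s_x = 10). The three interval estimators are

| approach     | center                       | half-width unit                 |
|--------------|------------------------------|---------------------------------|
| traditional  | `x`                          | `SEM = s_x√(1−r)`               |
| regression   | `ETS = M + r(x−M)`           | `SEE = s_x√r·√(1−r)`            |
| rets         | `RETS = M + √r(x−M)`         | `SERE = SEM` (identity)         |

with half-width `z·(unit)`, `z = Φ⁻¹(1 − (1−level)/2)`, level default 0.95.
The scale correction divides the centered ETS by the true-score SD
`s_t = s_x√r` and re-expands by `s_x`; its standard error inflates by the
same `1/√r`, which cancels the `√r` in the SEE — hence SERE ≡ SEM, and the
closed form is continuous at `r = 0`, where the interval becomes the
population prediction interval `M ± z·s_x`.

**Normal norming model (analytic oracle).** If `t ~ N(M, s_x²)` and
observed scores are linearly standardized to SD `s_x` (so `corr(t, x) = √r`),
then `t | x ~ N(RETS(x), SEM²)`. Conditional coverage of any of the three
intervals is a difference of normal CDFs; marginal coverage integrates over
`x ~ N(M, s_x²)` by Gauss–Hermite quadrature (129 nodes; differences vs a
20,001-point trapezoid integration are < 1e-9). The RETS interval has
conditional coverage exactly equal to the level at every `x`; the
traditional interval only at `x = M`; the regression interval's coverage
depends on `x` and `r` and tends to 0 pointwise as `r → 0`.

A subgroup mean may replace `M` as the regression target (`norm_mean`
argument) when the examinee's reference population is known a priori; the
interval width is unaffected.

## Synthetic cohorts

True scores: `t_j ~ N(M, s_x²)`. Item responses:

* **ordinal** — 10 items, 6 categories. Latent `y_ij = t_j + e_ij`,
  `e_ij ~ N(0, σ_e²)` homogeneous across items, cut by 5 shared thresholds
  into categories 1–6. Thresholds are equally spaced, symmetric about `M`,
  spanning ±2 total latent SDs (`√(s_x² + σ_e²)`); under the normal latent
  model this gives category probabilities (.023, .136, .341, .341, .136,
  .023) — skewness 0, excess kurtosis −0.19 — i.e. an approximately normal
  item-response histogram. A 6-point discretisation cannot be made exactly
  mesokurtic; the coverage results are insensitive to the exact spacing
  because sums of 10 items are close to normal regardless.
* **dichotomous** — 50 items; item `i` is solved when `y_ij` reaches a
  difficulty threshold `τ_i ~ N(M, s_x²)`, drawn once per study level.

Observed scores are item sums standardized to `(M, s_x)` using the
cohort's own sample mean/SD, so sample SD(observed) = SD(true) — the
norming convention under which RETS is the exact conditional center.

**Reliability calibration.** `σ_e` is tuned so Cronbach's alpha
(`k/(k−1)·(1 − Σ var_i / var_total)`, ddof = 1) of a dedicated calibration
cohort (n = 200,000, seed separate from evaluation) hits the nominal level
within 0.005. The calibration cohort's normal draws are frozen and reused
across candidate σ (common random numbers), making alpha a smooth,
strictly decreasing function of σ solved by Brent's method (≤ 60
iterations). The continuous-model closed form
`σ_e = √(k·s_x²(1−r)/r)` — exact for continuous item sums, an upper bound
after discretisation — initialises the bracket. Ordinal thresholds track
the candidate σ through the total latent SD so that the response
distribution stays near-normal at every trial point.

## Coverage study

Per reliability level (grid .10–.90): calibrate, simulate the evaluation
cohort, re-estimate alpha from the cohort's responses (the estimate, not
the nominal value, feeds the intervals — as a practitioner would), compute
all three 95% intervals per examinee with the full-population mean as
regression target, and tabulate the fraction of closed intervals covering
the true score: over all examinees, and conditionally at observed T = 50
and T ∈ {30, 70}.

**Binning on a discrete lattice.** "Observed T = 50" means the score
rounds to 50 (ties half-up). Standardized sums take at most
`k·(categories−1)+1` distinct values; at low reliability the lattice
spacing exceeds 1 T-unit (≈2.9 at alpha = .10 for the ordinal design) and a
1-unit window can contain no attainable score. In that case the bin falls
back to the examinees at the attainable value nearest the target — the
natural discrete analogue of conditioning on an unattainable score. This
lattice also causes small systematic offsets (up to ≈0.02) between
conditional-bin coverages and their continuous-model counterparts; the
"all"-scores column is unaffected.

**Problem sizes.** The package defaults to 10⁶ examinees per level (the
full-scale design). The bundled tests and the acceptance script run at
200,000 per level, where the "all" column has Monte-Carlo SE ≈ 0.0005 and
the conditional bins (≈1–4% of the cohort) have SE ≈ 0.003–0.010; test
tolerances for conditional bins therefore add a 3σ binomial allowance to
the 0.01 print resolution of the reference values.

**Determinism.** One root seed per study; child seeds are spawned
deterministically per (reliability level, purpose ∈ {design, calibration,
evaluation}) via `numpy.random.SeedSequence`, so levels are independent
and any subset of the grid reproduces identically.

## Reporting and rounding

Library functions never round. The report layer (CLI `score-ci`,
`manual-table`) rounds the point estimate and standard error to 2 decimals
and computes the printed bounds *from the rounded values*, the convention
of published test-manual tables, so a printed line is arithmetically
self-consistent (e.g. T = 60, r = .80 → RETS 58.94, SEM 4.47,
CI [50.18, 67.70]; at full precision the upper bound is 67.709).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `level` | 0.95 | two-sided confidence level; `z = 1.96` |
| `scale` | T (50, 10) | reporting scale; IQ (100, 15) predefined |
| `n_items`, `n_categories` | 10 × 6 ordinal / 50 × 2 dichotomous | test length and response format |
| `n` | 10⁶ | evaluation cohort per reliability level |
| `calib_n`, `calib_tol` | 200,000, 0.005 | calibration cohort and alpha tolerance |

## Limitations

* The generator draws homogeneous item errors and normal true scores; real
  tests show item-specific error variance, non-normal trait distributions
  and local dependence. Passing coverage here demonstrates correctness of
  the interval arithmetic under the CTT assumptions, not robustness to
  their violation.
* Dichotomous items violate CTT's linearity: item information peaks where
  difficulty matches the trait, so at high reliability the scale-corrected
  interval under-covers for extreme scores (≈.87–.89 at alpha = .90 for
  T = 30/70). Score-dependent intervals require an item-response-theory
  treatment, which is out of scope.
* Sampling variability of the norm statistics (M, s_x, reliability) is
  ignored: all intervals treat them as known.
* Restandardizing the ETS by its *observed* SD instead of the theoretical
  true-score SD would undo the regression adjustment and reproduce the
  traditional interval; this variant is deliberately not implemented.
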