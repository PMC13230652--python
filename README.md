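# truescoreci

Confidence intervals for **individual test scores** under classical test
theory (CTT), for psychologists, psychometricians and test developers who
report norm-referenced scores (T-scores, IQ scores, z-scores) and need an
interval for the examinee's *true* score that is both unbiased and
interpretable on the reporting scale.

## The problem and the three approaches

CTT writes an observed score as `x = t + e` with true score `t` and error
`e` uncorrelated. With reliability `r_xx` and observed-score SD `s_x`:

* **Traditional:** `CI = x ± z·SEM`, `SEM = s_x·√(1 − r_xx)`.
  Ignores regression to the mean: because observed and error scores
  correlate (`r_xe = √(1 − r_xx)`), true scores lie closer to the group
  mean than observed scores, so this interval under-covers for extreme
  scores.
* **Regression (Kelley):** `CI = ETS ± z·SEE`, with
  `ETS = M + r_xx·(x − M)` and `SEE = s_x·√r_xx·√(1 − r_xx)`.
  Statistically correct, but the ETS lives on a *shrunken* scale — true
  scores have SD `s_t = s_x·√r_xx` — so reading the interval as a T- or
  IQ-score is biased, and its width collapses to zero as `r_xx → 0`.
* **Regression with scale correction (recommended):**
  `CI = RETS ± z·SEM`, with `RETS = M + √r_xx·(x − M)`. The ETS is
  standardized by `s_t` and mapped back to the reporting scale; its
  standard error (SERE) equals the SEM exactly. Under the usual norming
  convention (observed scores standardized to the same mean and SD as the
  true scores) the conditional law of `t` given `x` is
  `Normal(RETS, SEM²)`, so this interval attains nominal coverage at
  *every* observed score.

The package provides the closed-form estimators, an analytic coverage
oracle (normal model, Gauss–Hermite quadrature), a synthetic item-response
generator (6-category Likert and dichotomous threshold models) with
reliability calibrated via Cronbach's alpha, and a Monte-Carlo coverage
study that tabulates how often each interval covers the simulated true
score, by reliability and by observed-score region.

## Worked example

An examinee scores T = 60 (scale mean 50, SD 10) on a test with
reliability .80:

```sh
$ truescoreci score-ci --x 60 --mean 50 --sd 10 -r 0.80 --method all
traditional  estimate 60.00  SE 4.47  95% CI [51.24, 68.76]
regression   estimate 58.00  SE 4.00  95% CI [50.16, 65.84]
rets         estimate 58.94  SE 4.47  95% CI [50.18, 67.70]
```

The scale-corrected estimate 58.94 = 50 + √.80·(60 − 50) acknowledges
regression to the mean (less aggressively than the raw ETS of 58, which is
on the wrong scale), and its interval [50.18, 67.70] can be read directly
as T-scores. Printed bounds are computed from the rounded estimate and SE,
as in test manuals, so each line's arithmetic is self-consistent.

The same numbers from Python:

```python
>>> import truescoreci as tc
>>> tc.rounded_report(60, tc.T_SCALE, 0.80)
RoundedReport(method='rets', observed=60.0, center=58.94, standard_error=4.47,
              lower=50.18, upper=67.7, level=0.95, decimals=2)
>>> tc.analytic_coverage("traditional", 0.10, x=70.0)   # tail under-coverage
0.6975911703548637
```

A small coverage simulation (3 reliability levels, 50,000 examinees,
10 six-category Likert items; the full study uses the nine-level grid
.10–.90 and 10⁶ examinees per level):

```sh
$ truescoreci -q simulate --config table1_smoke --out scratch/smoke
|   reliability |   traditional:all |   regression:all |   rets:all | ...
|           0.1 |              0.89 |             0.45 |       0.95 |
|           0.5 |              0.93 |             0.82 |       0.95 |
|           0.9 |              0.95 |             0.93 |       0.95 |
```

Only the scale-corrected approach holds the nominal 95% everywhere; the
uncorrected regression approach collapses at low reliability. Other
commands: `truescoreci manual-table` (publishable score-band tables),
`truescoreci figure1` (CI-width-vs-reliability panel figure).

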