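"""Closed-form CTT true-score estimators and confidence intervals.

Classical test theory decomposes an observed score ``x = t + e`` into a
true score and an uncorrelated error.  Three approaches to a confidence
interval for ``t`` given ``x`` are implemented:

``traditional``
    ``x ± z·SEM`` with ``SEM = s_x·sqrt(1 − r_xx)``.  Ignores regression
    to the mean, so it over-covers near the norm mean and under-covers in
    the tails.
``regression``
    Kelley's estimated true score ``ETS = M + r_xx·(x − M)`` with
    ``SEE = s_x·sqrt(r_xx)·sqrt(1 − r_xx)``.  Statistically correct, but
    the ETS lives on a shrunken scale (true scores have SD
    ``s_x·sqrt(r_xx)``), so interpreting the interval on the reporting
    scale is biased — pathologically so at low reliability, where the
    interval collapses to zero width.
``rets``
    The regression estimate rescaled back to the reporting scale:
    ``RETS = M + sqrt(r_xx)·(x − M)`` with standard error SERE, which is
    algebraically identical to the SEM.  Under the norming convention
    (true scores and standardized observed scores share mean and SD) the
    conditional distribution of the true score given ``x`` is exactly
    ``Normal(RETS, SEM²)``, so this interval attains nominal coverage at
    every observed score.

All functions broadcast over numpy arrays of observed scores.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy.stats import norm

from .scales import (
    ConfidenceInterval,
    NormScale,
    Reliability,
    TrueScoreEstimate,
    as_reliability,
)

__all__ = [
    "z_quantile",
    "sem",
    "see",
    "sere",
    "true_score_sd",
    "observed_error_correlation",
    "estimated_true_score",
    "rescaled_estimated_true_score",
    "expected_range",
    "ci_traditional",
    "ci_regression",
    "ci_rets",
    "point_estimate",
]

RelLike = Union[Reliability, float]


def z_quantile(level: float) -> float:
    """Two-sided standard-normal quantile for a confidence level.

    ``z = Phi^{-1}(1 − (1 − level)/2)``, e.g. 1.959964 for level 0.95.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie in (0, 1), got {level!r}")
    return float(norm.ppf(0.5 + level / 2.0))


def sem(scale: NormScale, rel: RelLike) -> float:
    """Standard error of measurement, ``s_x·sqrt(1 − r_xx)``.

    The SD of observed scores around a fixed true score.
    """
    r = as_reliability(rel).value
    return scale.sd * float(np.sqrt(1.0 - r))


def see(scale: NormScale, rel: RelLike) -> float:
    """Standard error of the regression-based ETS, ``s_x·sqrt(r)·sqrt(1 − r)``.

    Zero at both r = 0 and r = 1, maximal at r = 0.5 — the source of the
    regression approach's counterintuitive interval widths.
    """
    r = as_reliability(rel).value
    return scale.sd * float(np.sqrt(r) * np.sqrt(1.0 - r))


def sere(scale: NormScale, rel: RelLike) -> float:
    """Standard error of the rescaled (scale-corrected) estimate.

    Rescaling the ETS by ``1/sqrt(r)`` inflates the SEE by the same
    factor, giving ``s_x·sqrt(1 − r)`` — identical to the SEM.  The
    closed form is continuous at r = 0 (returns ``s_x``), which is also
    the Bayesian answer there: with a useless test, the posterior for the
    true score is the prior, SD ``s_x``.
    """
    return sem(scale, rel)


def true_score_sd(scale: NormScale, rel: RelLike) -> float:
    """SD of true scores across examinees, ``s_x·sqrt(r_xx)``.

    Follows from the definition of reliability as the true-score share of
    observed-score variance.
    """
    r = as_reliability(rel).value
    return scale.sd * float(np.sqrt(r))


def observed_error_correlation(rel: RelLike) -> float:
    """Correlation between observed scores and error scores, ``sqrt(1 − r_xx)``.

    Positive whenever reliability is imperfect; the mechanism behind
    regression to the mean.
    """
    r = as_reliability(rel).value
    return float(np.sqrt(1.0 - r))


def estimated_true_score(x, norm_mean: float, rel: RelLike):
    """Kelley's regression-based estimated true score ``M + r·(x − M)``.

    ``norm_mean`` is the mean of the reference group the examinee is
    drawn from; for an unselected examinee this is the norm-scale mean,
    but a subgroup mean (e.g. a clinical group's) is appropriate when
    group membership is known a priori.
    """
    r = as_reliability(rel).value
    x = np.asarray(x, dtype=float)
    out = norm_mean + r * (x - norm_mean)
    return float(out) if out.ndim == 0 else out


def rescaled_estimated_true_score(x, norm_mean: float, rel: RelLike):
    """Scale-corrected estimated true score ``M + sqrt(r)·(x − M)``.

    The ETS re-expressed on the reporting scale: standardize the ETS by
    the true-score SD ``s_x·sqrt(r)`` and map back through the scale's
    (mean, SD).  Lies between the ETS and the observed score.
    """
    r = as_reliability(rel).value
    x = np.asarray(x, dtype=float)
    out = norm_mean + np.sqrt(r) * (x - norm_mean)
    return float(out) if out.ndim == 0 else out


def _interval(center, half_width: float, level: float, method: str) -> ConfidenceInterval:
    center = np.asarray(center, dtype=float)
    lower = center - half_width
    upper = center + half_width
    if center.ndim == 0:
        center, lower, upper = float(center), float(lower), float(upper)
    return ConfidenceInterval(center=center, lower=lower, upper=upper, level=level, method=method)


def expected_range(
    true_score, scale: NormScale, rel: RelLike, level: float = 0.95
) -> ConfidenceInterval:
    """Expected range of *observed* scores for a given true score.

    ``t ± z·SEM``: the interval in which an examinee with true score ``t``
    would observe their score with the stated probability.  Not a
    confidence interval for the true score, but its historical template.
    """
    return _interval(true_score, z_quantile(level) * sem(scale, rel), level, "expected_range")


def ci_traditional(x, scale: NormScale, rel: RelLike, level: float = 0.95) -> ConfidenceInterval:
    """Traditional confidence interval ``x ± z·SEM``."""
    return _interval(x, z_quantile(level) * sem(scale, rel), level, "traditional")


def ci_regression(
    x,
    scale: NormScale,
    rel: RelLike,
    level: float = 0.95,
    norm_mean: Optional[float] = None,
) -> ConfidenceInterval:
    """Regression-approach confidence interval ``ETS ± z·SEE``.

    ``norm_mean`` overrides the scale mean as the regression target
    (subgroup norming); defaults to ``scale.mean``.
    """
    m = scale.mean if norm_mean is None else float(norm_mean)
    center = estimated_true_score(x, m, rel)
    return _interval(center, z_quantile(level) * see(scale, rel), level, "regression")


def ci_rets(
    x,
    scale: NormScale,
    rel: RelLike,
    level: float = 0.95,
    norm_mean: Optional[float] = None,
) -> ConfidenceInterval:
    """Scale-corrected regression confidence interval ``RETS ± z·SEM``.

    The recommended interval: centered on the rescaled estimated true
    score, with the traditional SEM as half-width unit.  At r = 0 it
    degenerates gracefully to the population prediction interval
    ``M ± z·s_x``.
    """
    m = scale.mean if norm_mean is None else float(norm_mean)
    center = rescaled_estimated_true_score(x, m, rel)
    return _interval(center, z_quantile(level) * sere(scale, rel), level, "rets")


def point_estimate(
    x,
    scale: NormScale,
    rel: RelLike,
    method: str = "rets",
    norm_mean: Optional[float] = None,
) -> TrueScoreEstimate:
    """Point estimate and standard error for one of the three approaches."""
    m = scale.mean if norm_mean is None else float(norm_mean)
    if method == "traditional":
        center, se = np.asarray(x, dtype=float), sem(scale, rel)
    elif method == "regression":
        center, se = estimated_true_score(x, m, rel), see(scale, rel)
    elif method == "rets":
        center, se = rescaled_estimated_true_score(x, m, rel), sere(scale, rel)
    else:
        raise ValueError(f"unknown estimation method {method!r}")
    if np.ndim(center) == 0:
        center = float(center)
    return TrueScoreEstimate(center=center, standard_error=se, method=method)
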