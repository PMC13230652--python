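"""Norm scales, reliability coefficients, and result containers.

Classical test theory (CTT) reports scores on a *norm scale* — a linear
transformation of raw scores fixed by a norming sample, e.g. the T scale
(mean 50, SD 10) or the IQ scale (mean 100, SD 15).  All estimators in
:mod:`truescoreci.ctt` are parameterised by such a scale together with a
reliability coefficient ``r_xx`` (the proportion of observed-score variance
attributable to true scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "NormScale",
    "Reliability",
    "TrueScoreEstimate",
    "ConfidenceInterval",
    "ScaleDiagnostics",
    "T_SCALE",
    "IQ_SCALE",
    "as_reliability",
]

#: Tolerance for numeric excursions of a reliability outside [0, 1]
#: (e.g. a sample Cronbach's alpha of 1 + 1e-16); anything further out
#: is a hard error because the CTT formulas take square roots of
#: ``r`` and ``1 - r``.
_RELIABILITY_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class NormScale:
    """Reporting scale of observed scores: mean and standard deviation.

    The mean of true scores is assumed equal to the mean of observed
    scores on this scale (errors have expectation zero), so ``mean``
    doubles as the default regression target.
    """

    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"scale mean must be finite, got {self.mean!r}")
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"scale sd must be a positive real, got {self.sd!r}")


#: Standard T scale (M = 50, SD = 10), common for questionnaires.
T_SCALE = NormScale(50.0, 10.0, "T")
#: IQ scale (M = 100, SD = 15), common for ability tests.
IQ_SCALE = NormScale(100.0, 15.0, "IQ")


@dataclass(frozen=True)
class Reliability:
    """Reliability coefficient ``r_xx`` in [0, 1].

    ``source`` records whether the value is treated as known (e.g. from a
    test manual) or was estimated as Cronbach's alpha from item responses.
    Values outside [0, 1] by more than a tiny numeric tolerance raise;
    tiny excursions (floating-point noise) are clamped.
    """

    value: float
    source: str = "known"

    def __post_init__(self) -> None:
        v = float(self.value)
        if not np.isfinite(v):
            raise ValueError(f"reliability must be finite, got {self.value!r}")
        if v < -_RELIABILITY_CLAMP_TOL or v > 1.0 + _RELIABILITY_CLAMP_TOL:
            raise ValueError(
                f"reliability must lie in [0, 1], got {v!r} "
                "(a sample estimate outside this range cannot be used: "
                "the CTT formulas take sqrt(r) and sqrt(1 - r))"
            )
        object.__setattr__(self, "value", min(max(v, 0.0), 1.0))
        if self.source not in ("known", "cronbach_alpha"):
            raise ValueError(f"unknown reliability source {self.source!r}")


def as_reliability(rel: Union[Reliability, float]) -> Reliability:
    """Coerce a bare float to a :class:`Reliability` (source ``known``)."""
    if isinstance(rel, Reliability):
        return rel
    return Reliability(float(rel))


@dataclass(frozen=True)
class TrueScoreEstimate:
    """Point estimate of an examinee's true score with its standard error.

    ``method`` is one of ``traditional`` (center = observed score, SE =
    SEM), ``regression`` (center = ETS, SE = SEE) or ``rets`` (center =
    scale-corrected RETS, SE = SERE = SEM).
    """

    center: float
    standard_error: float
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("traditional", "regression", "rets"):
            raise ValueError(f"unknown estimation method {self.method!r}")
        if np.any(np.asarray(self.standard_error) < 0):
            raise ValueError("standard_error must be nonnegative")


@dataclass(frozen=True)
class ConfidenceInterval:
    """Symmetric two-sided confidence interval for a true score.

    Fields may be scalars or (for vectorised cohort computations)
    equally-shaped numpy arrays.
    """

    center: Union[float, np.ndarray]
    lower: Union[float, np.ndarray]
    upper: Union[float, np.ndarray]
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must lie in (0, 1), got {self.level!r}")
        if self.method not in ("traditional", "regression", "rets", "expected_range"):
            raise ValueError(f"unknown interval method {self.method!r}")
        # tolerance absorbs floating-point noise in degenerate (zero-width) cases
        if not (
            np.all(np.asarray(self.lower) <= np.asarray(self.center) + 1e-12)
            and np.all(np.asarray(self.center) <= np.asarray(self.upper) + 1e-12)
        ):
            raise ValueError("interval must satisfy lower <= center <= upper")

    @property
    def width(self) -> Union[float, np.ndarray]:
        return np.asarray(self.upper) - np.asarray(self.lower)

    def contains(self, value) -> Union[bool, np.ndarray]:
        """Closed-interval membership test (boundary counts as covered)."""
        v = np.asarray(value)
        return (np.asarray(self.lower) <= v) & (v <= np.asarray(self.upper))


@dataclass(frozen=True)
class ScaleDiagnostics:
    """Derived quantities of a (scale, reliability) pair.

    ``true_score_sd`` is ``s_x * sqrt(r_xx)``: true scores are less
    dispersed than observed scores under imperfect reliability — the fact
    that motivates the scale correction.  ``observed_error_correlation``
    is ``sqrt(1 - r_xx)``, the correlation between observed scores and
    error scores that produces regression to the mean.
    """

    true_score_sd: float
    observed_error_correlation: float

    @classmethod
    def from_scale(cls, scale: NormScale, rel: Union[Reliability, float]) -> "ScaleDiagnostics":
        r = as_reliability(rel).value
        return cls(
            true_score_sd=scale.sd * float(np.sqrt(r)),
            observed_error_correlation=float(np.sqrt(1.0 - r)),
        )
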