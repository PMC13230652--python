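"""Presentation-layer rounding of score reports.

Test manuals and score reports print the point estimate, its standard
error and the confidence bounds rounded to a fixed number of decimals,
and the printed bounds are computed *from the printed (rounded) estimate
and standard error* so that a reader can verify the arithmetic of the
report line by line.  This module implements that convention; the
library functions in :mod:`truescoreci.ctt` always work at full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from . import ctt
from .scales import NormScale, Reliability

__all__ = ["RoundedReport", "rounded_report"]


@dataclass(frozen=True)
class RoundedReport:
    """One printed report line: estimate, SE, and self-consistent bounds."""

    method: str
    observed: float
    center: float
    standard_error: float
    lower: float
    upper: float
    level: float
    decimals: int


def rounded_report(
    x: float,
    scale: NormScale,
    rel: Union[Reliability, float],
    method: str = "rets",
    level: float = 0.95,
    norm_mean: Optional[float] = None,
    decimals: int = 2,
) -> RoundedReport:
    """Score report with manual-style rounding.

    The center and standard error are rounded to ``decimals`` places;
    the bounds are then ``center ± z·SE`` computed from those rounded
    values and rounded again, so the printed line is internally
    consistent (e.g. T = 60, reliability .80: RETS 58.94, SEM 4.47,
    95% CI [50.18, 67.70]).
    """
    est = ctt.point_estimate(x, scale, rel, method=method, norm_mean=norm_mean)
    z = ctt.z_quantile(level)
    center = round(float(est.center), decimals)
    se = round(float(est.standard_error), decimals)
    return RoundedReport(
        method=method,
        observed=float(x),
        center=center,
        standard_error=se,
        lower=round(center - z * se, decimals),
        upper=round(center + z * se, decimals),
        level=level,
        decimals=decimals,
    )
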