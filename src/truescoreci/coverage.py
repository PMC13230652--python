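"""Empirical and analytic coverage of true-score confidence intervals.

The coverage study simulates a large cohort of examinees, computes all
three confidence intervals for each observed score using a reliability
estimated from the cohort's own item responses (Cronbach's alpha), and
tabulates the fraction of intervals covering the underlying true score —
overall and conditionally on extreme / central observed scores.

A closed-form oracle is provided for the *normal norming model*: true
scores Normal(M, s_x²), observed scores linearly standardized so both
share SD s_x, correlation sqrt(r_xx).  There the conditional law of the
true score given an observed score x is Normal(RETS(x), SEM²), so the
conditional coverage of each interval is a difference of normal CDFs and
the marginal coverage follows by Gauss–Hermite quadrature over x.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import ctt
from .scales import ConfidenceInterval, NormScale, Reliability, T_SCALE, as_reliability
from .simulate import (
    ItemModelSpec,
    calibrate_error_sd,
    cronbach_alpha,
    draw_dichotomous_thresholds,
    draw_true_scores,
    simulate_responses,
    sum_and_standardize,
    _spec_with_error_sd,
)

__all__ = [
    "APPROACHES",
    "SCORE_BINS",
    "CoverageCell",
    "CoverageTable",
    "CoverageStudyConfig",
    "bin_observed_scores",
    "empirical_coverage",
    "analytic_coverage",
    "run_coverage_study",
]

APPROACHES = ("traditional", "regression", "rets")
SCORE_BINS = ("T50", "T30or70", "all")

_CI_FUNCS = {
    "traditional": ctt.ci_traditional,
    "regression": ctt.ci_regression,
    "rets": ctt.ci_rets,
}


@dataclass(frozen=True)
class CoverageCell:
    """One table cell: coverage of one approach at one reliability and bin."""

    reliability_level: float
    approach: str
    score_bin: str
    coverage: float
    n_in_bin: int

    def __post_init__(self) -> None:
        if self.n_in_bin < 0:
            raise ValueError("n_in_bin must be nonnegative")
        if self.n_in_bin == 0:
            if not np.isnan(self.coverage):
                raise ValueError("coverage of an empty bin must be NaN")
        elif not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")


@dataclass(frozen=True)
class CoverageStudyConfig:
    """Design of one coverage simulation (one item kind, a reliability grid).

    Defaults reproduce the full-scale study design: cohorts of 10⁶
    examinees per reliability level, nominal reliabilities .10–.90, 10
    six-category ordinal items or 50 dichotomous items, true scores on
    the T scale, 95% intervals, alpha re-estimated on each cohort.
    """

    item_kind: str = "ordinal"
    n: int = 1_000_000
    reliability_grid: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    level: float = 0.95
    seed: int = 0
    calib_n: int = 200_000
    calib_tol: float = 0.005
    n_items: Optional[int] = None  # default: 10 ordinal / 50 dichotomous
    n_categories: int = 6
    scale: NormScale = T_SCALE

    def __post_init__(self) -> None:
        if self.item_kind not in ("ordinal", "dichotomous"):
            raise ValueError(f"unknown item kind {self.item_kind!r}")
        if self.n < 2 or self.calib_n < 2:
            raise ValueError("cohort sizes must be >= 2")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        for r in self.reliability_grid:
            if not (0.0 < r < 1.0):
                raise ValueError("reliability grid values must lie in (0, 1)")

    @property
    def items(self) -> int:
        if self.n_items is not None:
            return self.n_items
        return 10 if self.item_kind == "ordinal" else 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scale"] = {"mean": self.scale.mean, "sd": self.scale.sd, "label": self.scale.label}
        d["reliability_grid"] = list(self.reliability_grid)
        d["n_items"] = self.items
        return d


@dataclass(frozen=True)
class CoverageTable:
    """Coverage proportions indexed by reliability × approach × score bin."""

    item_kind: str
    cells: tuple
    config: CoverageStudyConfig
    achieved_alphas: dict = field(default_factory=dict)

    def get(self, reliability_level: float, approach: str, score_bin: str) -> CoverageCell:
        for c in self.cells:
            if (
                abs(c.reliability_level - reliability_level) < 1e-9
                and c.approach == approach
                and c.score_bin == score_bin
            ):
                return c
        raise KeyError((reliability_level, approach, score_bin))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_kind": self.item_kind,
                "reliability": c.reliability_level,
                "approach": c.approach,
                "bin": c.score_bin,
                "n_in_bin": c.n_in_bin,
                "coverage": c.coverage,
            }
            for c in self.cells
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_markdown(self) -> str:
        """Wide layout: one row per reliability, approach × bin columns."""
        df = self.to_dataframe()
        wide = df.pivot_table(
            index="reliability", columns=["approach", "bin"], values="coverage"
        )
        cols = [(a, b) for a in APPROACHES for b in SCORE_BINS]
        wide = wide.loc[:, cols]
        wide.columns = [f"{a}:{b}" for a, b in cols]
        return wide.round(2).to_markdown()


def _target_mask(x: np.ndarray, target: float) -> np.ndarray:
    """Scores matching one target T-value: those rounding to it (nearest
    integer, ties half-up), or — when standardized sum scores form a
    lattice coarser than the 1-unit window, leaving it empty — the scores
    at the attainable value nearest the target."""
    mask = np.floor(x + 0.5) == target
    if not mask.any() and x.size:
        nearest = x[np.argmin(np.abs(x - target))]
        mask = x == nearest
    return mask


def bin_observed_scores(observed: Sequence[float]) -> dict:
    """Boolean masks for the reporting bins of observed norm scores.

    A score belongs to ``T50`` if it rounds to 50, to ``T30or70`` if it
    rounds to 30 or 70 (with the nearest-attainable-value fallback of
    :func:`_target_mask` applied per target), and every score belongs to
    ``all``.
    """
    x = np.asarray(observed, dtype=float)
    return {
        "T50": _target_mask(x, 50.0),
        "T30or70": _target_mask(x, 30.0) | _target_mask(x, 70.0),
        "all": np.ones(x.shape, dtype=bool),
    }


def empirical_coverage(
    true_scores: Sequence[float],
    intervals: Union[ConfidenceInterval, tuple],
) -> float:
    """Fraction of closed intervals containing the true score.

    ``intervals`` is either an array-valued :class:`ConfidenceInterval`
    or a ``(lower, upper)`` pair of arrays matched to ``true_scores``.
    """
    t = np.asarray(true_scores, dtype=float)
    if isinstance(intervals, ConfidenceInterval):
        lower, upper = np.asarray(intervals.lower), np.asarray(intervals.upper)
    else:
        lower, upper = (np.asarray(a, dtype=float) for a in intervals)
    lower, upper = np.broadcast_to(lower, t.shape), np.broadcast_to(upper, t.shape)
    return float(np.mean((lower <= t) & (t <= upper)))


def _conditional_coverage(
    approach: str, x: np.ndarray, r: float, scale: NormScale, level: float, norm_mean: float
) -> np.ndarray:
    """Coverage of one approach's interval at observed score(s) x under the
    normal norming model, where T | X=x ~ Normal(RETS(x), SEM²)."""
    x = np.asarray(x, dtype=float)
    cond_mean = ctt.rescaled_estimated_true_score(x, norm_mean, r)
    cond_sd = ctt.sem(scale, r)
    z = ctt.z_quantile(level)
    if approach == "traditional":
        center, half = x, z * ctt.sem(scale, r)
    elif approach == "regression":
        center = ctt.estimated_true_score(x, norm_mean, r)
        half = z * ctt.see(scale, r)
    elif approach == "rets":
        center, half = cond_mean, z * ctt.sere(scale, r)
    else:
        raise ValueError(f"unknown approach {approach!r}")
    if cond_sd == 0.0:  # perfect reliability: conditional law degenerate at x
        return ((center - half <= cond_mean) & (cond_mean <= center + half)).astype(float)
    return norm.cdf((center + half - cond_mean) / cond_sd) - norm.cdf(
        (center - half - cond_mean) / cond_sd
    )


def analytic_coverage(
    approach: str,
    rel: Union[Reliability, float],
    scale: NormScale = T_SCALE,
    level: float = 0.95,
    x: Optional[float] = None,
    norm_mean: Optional[float] = None,
    n_quad: int = 129,
) -> float:
    """Exact coverage under the normal norming model.

    With ``x`` given, the conditional coverage of the approach's interval
    at that observed score; with ``x`` omitted, the marginal coverage
    over X ~ Normal(M, s_x²) by Gauss–Hermite quadrature.  The RETS
    interval has conditional coverage exactly ``level`` at every x; the
    traditional interval attains ``level`` only at x = M; the regression
    interval's coverage depends on both x and r.
    """
    r = as_reliability(rel).value
    m = scale.mean if norm_mean is None else float(norm_mean)
    if x is not None:
        return float(_conditional_coverage(approach, np.asarray(x), r, scale, level, m))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    xs = m + np.sqrt(2.0) * scale.sd * nodes
    cov = _conditional_coverage(approach, xs, r, scale, level, m)
    return float(np.sum(weights * cov) / np.sqrt(np.pi))


def _study_spec_template(config: CoverageStudyConfig, thresholds: Optional[np.ndarray]) -> ItemModelSpec:
    if config.item_kind == "ordinal":
        return ItemModelSpec(
            kind="ordinal",
            n_items=config.items,
            n_categories=config.n_categories,
            latent_error_sd=1.0,  # placeholder; calibration sets it
        )
    return ItemModelSpec(
        kind="dichotomous",
        n_items=config.items,
        latent_error_sd=1.0,
        dichotomous_thresholds=thresholds,
    )


def run_coverage_study(config: CoverageStudyConfig, progress=None) -> CoverageTable:
    """Run the full coverage simulation for one item kind.

    Per reliability level: draw the test design (dichotomous difficulty
    thresholds where applicable), calibrate the item-error SD to the
    nominal reliability on a dedicated calibration cohort, simulate the
    evaluation cohort, estimate Cronbach's alpha from its responses,
    standardize sum scores to the norm scale, compute all three 95%
    intervals per examinee using the *estimated* alpha, and tabulate
    coverage per score bin.  Child seeds are derived deterministically
    per (level, purpose), so levels are independent and the study is
    reproducible from (config, seed) alone.
    """
    cells: list[CoverageCell] = []
    alphas: dict[float, float] = {}
    for level_r in config.reliability_grid:
        centi = int(round(level_r * 100))
        design_seed = np.random.SeedSequence([config.seed, centi, 0])
        calib_seed = np.random.SeedSequence([config.seed, centi, 1])
        eval_seed = np.random.SeedSequence([config.seed, centi, 2])

        thresholds = None
        if config.item_kind == "dichotomous":
            thresholds = draw_dichotomous_thresholds(config.items, config.scale, design_seed)
        template = _study_spec_template(config, thresholds)

        calib = calibrate_error_sd(
            template,
            level_r,
            config.scale,
            calib_n=config.calib_n,
            seed=calib_seed,
            tol=config.calib_tol,
        )
        spec = _spec_with_error_sd(template, calib.latent_error_sd, config.scale)

        rng = np.random.default_rng(eval_seed)
        t = draw_true_scores(config.n, config.scale, rng)
        responses = simulate_responses(t, spec, rng)
        alpha = cronbach_alpha(responses)
        alphas[level_r] = alpha
        observed = sum_and_standardize(responses, config.scale)
        rel = Reliability(alpha, source="cronbach_alpha")

        masks = bin_observed_scores(observed)
        for approach in APPROACHES:
            ci = _CI_FUNCS[approach](observed, config.scale, rel, config.level)
            covered = (np.asarray(ci.lower) <= t) & (t <= np.asarray(ci.upper))
            for bin_name in SCORE_BINS:
                mask = masks[bin_name]
                n_bin = int(mask.sum())
                # discrete sum scores can leave a narrow bin empty at low
                # reliability; an empty bin has no defined coverage
                cov = float(covered[mask].mean()) if n_bin else float("nan")
                cells.append(
                    CoverageCell(
                        reliability_level=level_r,
                        approach=approach,
                        score_bin=bin_name,
                        coverage=cov,
                        n_in_bin=n_bin,
                    )
                )
        if progress is not None:
            progress(level_r, alpha)
    return CoverageTable(
        item_kind=config.item_kind,
        cells=tuple(cells),
        config=config,
        achieved_alphas=alphas,
    )
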