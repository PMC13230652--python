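"""Synthetic item-response cohorts with calibrated reliability.

Two generative models for test data, both driven by normally distributed
true scores on a norm scale:

* **ordinal** (Likert questionnaires): each item's latent response is the
  true score plus item-specific normal error, discretised into ordered
  categories by a shared set of ascending thresholds chosen so that the
  marginal category distribution is approximately normal;
* **dichotomous** (ability tests): an item is solved when the latent
  response exceeds that item's difficulty threshold; thresholds vary
  across items, drawn from the norm distribution.

The per-item error SD is the single dial controlling reliability; it is
calibrated by root-finding so that Cronbach's alpha of a large calibration
cohort hits a target.  Observed scores are the item sums, linearly
standardized to the norm scale — which makes the SD of standardized
observed scores equal that of the true scores, the norming convention
under which the scale-corrected regression interval is the exact
conditional interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .scales import NormScale

__all__ = [
    "ItemModelSpec",
    "SimulatedCohort",
    "CalibrationResult",
    "draw_true_scores",
    "default_ordinal_thresholds",
    "draw_dichotomous_thresholds",
    "simulate_responses",
    "cronbach_alpha",
    "sum_and_standardize",
    "closed_form_error_sd",
    "calibrate_error_sd",
    "make_cohort",
    "continuous_cohort",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ItemModelSpec:
    """Generative model for one simulated test.

    ``latent_error_sd`` is the SD of the per-item error ``e_ij`` in
    norm-scale units (homogeneous across items).  For ordinal items,
    ``ordinal_thresholds`` are the ``n_categories − 1`` shared cutoffs of
    the latent response; for dichotomous items, ``dichotomous_thresholds``
    are the per-item difficulty cutoffs.
    """

    kind: str  # "ordinal" | "dichotomous"
    n_items: int
    latent_error_sd: float
    n_categories: int = 2
    ordinal_thresholds: Optional[np.ndarray] = None
    dichotomous_thresholds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal", "dichotomous"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if not (self.latent_error_sd > 0):
            raise ValueError("latent_error_sd must be positive")
        if self.kind == "ordinal":
            if self.n_categories < 2:
                raise ValueError("ordinal items need at least 2 categories")
            if self.ordinal_thresholds is not None:
                t = np.asarray(self.ordinal_thresholds, dtype=float)
                if t.shape != (self.n_categories - 1,):
                    raise ValueError(
                        f"expected {self.n_categories - 1} ordinal thresholds, got {t.shape}"
                    )
                if not np.all(np.diff(t) > 0):
                    raise ValueError("ordinal thresholds must be strictly ascending")
                object.__setattr__(self, "ordinal_thresholds", t)
        else:
            if self.n_categories != 2:
                raise ValueError("dichotomous items have exactly 2 categories")
            if self.dichotomous_thresholds is not None:
                t = np.asarray(self.dichotomous_thresholds, dtype=float)
                if t.shape != (self.n_items,):
                    raise ValueError(
                        f"expected {self.n_items} dichotomous thresholds, got {t.shape}"
                    )
                object.__setattr__(self, "dichotomous_thresholds", t)


@dataclass(frozen=True)
class SimulatedCohort:
    """True scores, item responses and standardized observed scores."""

    true_scores: np.ndarray
    responses: np.ndarray
    observed_scores: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.true_scores)
        if self.responses.shape[0] != n or len(self.observed_scores) != n:
            raise ValueError("cohort arrays have inconsistent lengths")

    @property
    def n_participants(self) -> int:
        return len(self.true_scores)

    def to_dataframe(self) -> pd.DataFrame:
        k = self.responses.shape[1]
        df = pd.DataFrame(
            {
                "participant_id": np.arange(self.n_participants),
                "true_score": self.true_scores,
                "observed_T": self.observed_scores,
            }
        )
        for i in range(k):
            df[f"item_{i + 1}"] = self.responses[:, i]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of tuning the item-error SD to a target Cronbach's alpha."""

    latent_error_sd: float
    achieved_alpha: float
    target_reliability: float
    iterations: int


def draw_true_scores(n: int, scale: NormScale, seed: SeedLike) -> np.ndarray:
    """Draw ``n`` true scores from Normal(scale.mean, scale.sd²)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _rng(seed).normal(scale.mean, scale.sd, size=n)


def default_ordinal_thresholds(
    n_categories: int, total_latent_sd: float, scale: NormScale
) -> np.ndarray:
    """Equally spaced category cutoffs, symmetric about the scale mean.

    The ``n_categories − 1`` cutoffs span ±2 total latent SDs
    (``sqrt(sigma_t² + sigma_e²)``) around the mean.  Under a normal
    latent response this yields a symmetric, approximately normal
    category histogram (skewness 0; excess kurtosis ≈ −0.19 for six
    categories).  For two categories the single cutoff sits at the mean.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    if not (total_latent_sd > 0):
        raise ValueError("total_latent_sd must be positive")
    if n_categories == 2:  # a single cutoff sits at the mean by symmetry
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-2.0, 2.0, n_categories - 1)
    return scale.mean + total_latent_sd * offsets


def draw_dichotomous_thresholds(n_items: int, scale: NormScale, seed: SeedLike) -> np.ndarray:
    """Per-item difficulty cutoffs, i.i.d. Normal(scale.mean, scale.sd²)."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    return _rng(seed).normal(scale.mean, scale.sd, size=n_items)


def simulate_responses(
    true_scores: Sequence[float], spec: ItemModelSpec, seed: SeedLike
) -> np.ndarray:
    """Simulate the item-response matrix for given true scores.

    Latent response ``y_ij = t_j + e_ij`` with ``e_ij ~ Normal(0,
    latent_error_sd²)``.  Ordinal items discretise ``y`` by the shared
    thresholds into categories ``1..n_categories``; dichotomous items
    score 1 when ``y_ij`` reaches the item's difficulty threshold.
    """
    t = np.asarray(true_scores, dtype=float)
    if t.ndim != 1:
        raise ValueError("true_scores must be one-dimensional")
    rng = _rng(seed)
    errors = rng.normal(0.0, spec.latent_error_sd, size=(t.size, spec.n_items))
    latent = t[:, None] + errors
    return _discretize(latent, spec)


def _discretize(latent: np.ndarray, spec: ItemModelSpec) -> np.ndarray:
    if spec.kind == "ordinal":
        if spec.ordinal_thresholds is None:
            raise ValueError("ordinal spec is missing thresholds")
        return (
            np.searchsorted(spec.ordinal_thresholds, latent).astype(np.int8) + 1
        )
    if spec.dichotomous_thresholds is None:
        raise ValueError("dichotomous spec is missing thresholds")
    return (latent >= spec.dichotomous_thresholds[None, :]).astype(np.int8)


def cronbach_alpha(responses: np.ndarray) -> float:
    """Cronbach's alpha, ``k/(k−1)·(1 − Σ var(item_i) / var(sum))``.

    Sample variances with denominator ``n − 1``.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 participants and >= 2 items")
    k = r.shape[1]
    total_var = r.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    item_var = r.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def sum_and_standardize(responses: np.ndarray, scale: NormScale) -> np.ndarray:
    """Sum scores linearly standardized to the norm scale.

    Uses the cohort's own sample mean and SD (ddof=1), so the output has
    sample mean ``scale.mean`` and sample SD ``scale.sd`` exactly.
    """
    sums = np.asarray(responses, dtype=float).sum(axis=1)
    sd = sums.std(ddof=1)
    if sd <= 0:
        raise ValueError("sum scores have zero variance; cannot standardize")
    return scale.mean + scale.sd * (sums - sums.mean()) / sd


def closed_form_error_sd(n_items: int, target_rel: float, scale: NormScale) -> float:
    """Item-error SD giving reliability ``r`` for *continuous* item sums.

    For ``k`` parallel continuous items, the sum's reliability is
    ``k·σ_t² / (k·σ_t² + σ_e²)``, so ``σ_e = sqrt(k·σ_t²·(1 − r)/r)``.
    Discretisation discards information, so the calibrated SD for
    categorical items is smaller than this bound.
    """
    if not (0.0 < target_rel < 1.0):
        raise ValueError("target reliability must lie in (0, 1)")
    return float(np.sqrt(n_items * scale.sd**2 * (1.0 - target_rel) / target_rel))


def _spec_with_error_sd(
    template: ItemModelSpec, sigma_e: float, scale: NormScale
) -> ItemModelSpec:
    """Fill in the error SD and, for ordinal items, the matching thresholds.

    Ordinal thresholds track the total latent SD so that the category
    histogram stays near-normal at every candidate error SD.
    """
    if template.kind == "ordinal":
        thresholds = default_ordinal_thresholds(
            template.n_categories, float(np.hypot(scale.sd, sigma_e)), scale
        )
        return replace(template, latent_error_sd=sigma_e, ordinal_thresholds=thresholds)
    return replace(template, latent_error_sd=sigma_e)


def calibrate_error_sd(
    spec_template: ItemModelSpec,
    target_rel: float,
    scale: NormScale,
    calib_n: int = 200_000,
    seed: SeedLike = 0,
    tol: float = 0.005,
) -> CalibrationResult:
    """Find the item-error SD whose cohort Cronbach's alpha hits a target.

    A single calibration cohort (true scores and standard-normal item
    errors) is drawn once and reused across candidate SDs (common random
    numbers), making alpha a smooth, strictly decreasing function of the
    error SD that is solved by Brent's method.  The bracket starts at the
    continuous-model closed form (an upper bound, since discretisation
    loses information) and a small fraction of it.

    Raises a RuntimeError if no bracket is found or the root search does
    not converge within 60 iterations.
    """
    if not (0.0 < target_rel < 1.0):
        raise ValueError("target reliability must lie in (0, 1)")
    rng = _rng(seed)
    t = draw_true_scores(calib_n, scale, rng)
    z = rng.standard_normal((calib_n, spec_template.n_items))

    def achieved(sigma_e: float) -> float:
        spec = _spec_with_error_sd(spec_template, sigma_e, scale)
        responses = _discretize(t[:, None] + sigma_e * z, spec)
        return cronbach_alpha(responses)

    upper = closed_form_error_sd(spec_template.n_items, target_rel, scale)
    lo, hi = 1e-3 * upper, upper
    f_lo, f_hi = achieved(lo) - target_rel, achieved(hi) - target_rel
    expansions = 0
    while f_hi > 0 and expansions < 8:  # discretisation can be mild; widen upward
        hi *= 2.0
        f_hi = achieved(hi) - target_rel
        expansions += 1
    if f_lo < 0 or f_hi > 0:
        raise RuntimeError(
            f"could not bracket alpha={target_rel} (alpha range "
            f"[{f_hi + target_rel:.4f}, {f_lo + target_rel:.4f}])"
        )
    sigma, res = optimize.brentq(
        lambda s: achieved(s) - target_rel,
        lo,
        hi,
        xtol=1e-4 * upper,
        maxiter=60,
        full_output=True,
    )
    if not res.converged:
        raise RuntimeError("error-SD calibration did not converge within 60 iterations")
    alpha = achieved(sigma)
    if abs(alpha - target_rel) > tol:
        raise RuntimeError(
            f"calibration landed at alpha={alpha:.4f}, outside tolerance "
            f"{tol} of target {target_rel}"
        )
    return CalibrationResult(
        latent_error_sd=float(sigma),
        achieved_alpha=float(alpha),
        target_reliability=float(target_rel),
        iterations=int(res.iterations) + expansions,
    )


def make_cohort(
    spec: ItemModelSpec, n: int, scale: NormScale, seed: int
) -> SimulatedCohort:
    """Draw a full cohort: true scores, responses, standardized sums."""
    ss = np.random.SeedSequence(seed)
    true_seed, resp_seed = ss.spawn(2)
    t = draw_true_scores(n, scale, true_seed)
    responses = simulate_responses(t, spec, resp_seed)
    observed = sum_and_standardize(responses, scale)
    return SimulatedCohort(
        true_scores=t, responses=responses, observed_scores=observed, seed=seed
    )


def continuous_cohort(
    n: int, reliability: float, scale: NormScale, seed: SeedLike
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-score cohort with known reliability (no items).

    Observed raw scores are ``t + e`` with ``e ~ Normal(0, σ_e²)`` and
    ``σ_e = s_x·sqrt((1 − r)/r)``, then standardized to the norm scale.
    The analytic normal norming model holds exactly here, which makes
    this cohort the Monte-Carlo counterpart of the quadrature coverage
    oracle.  Returns ``(true_scores, observed_scores)``.
    """
    if not (0.0 < reliability <= 1.0):
        raise ValueError("reliability must lie in (0, 1]")
    rng = _rng(seed)
    t = draw_true_scores(n, scale, rng)
    if reliability == 1.0:
        raw = t.copy()
    else:
        sigma_e = scale.sd * np.sqrt((1.0 - reliability) / reliability)
        raw = t + rng.normal(0.0, sigma_e, size=n)
    observed = scale.mean + scale.sd * (raw - raw.mean()) / raw.std(ddof=1)
    return t, observed
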