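"""Statistical plan: nonparametric screening, Enter-method regression, diagnostics.

The analysis mirrors a conventional survey workflow on ordinal demand
scores:

1. Univariate screening per demographic factor — Mann–Whitney U (two
   groups, reported as a tie-corrected normal-approximation Z) or
   Kruskal–Wallis H (three or more groups, chi-square reference on k−1
   degrees of freedom).  Factors with p < 0.05 for a dimension enter its
   multivariable model.
2. Ordinary least squares on the dimension score with all screened factors
   entered simultaneously (the "Enter" strategy — no stepwise selection),
   dummy-coded against fixed reference categories (age 60–65, junior-high
   education or below, with spouse, ≤1 child, not living alone, fully
   independent, no chronic disease, income 0–1,500).
3. Collinearity diagnostics (tolerance = 1 − R²_aux, VIF = 1/tolerance from
   auxiliary regressions) and the Durbin–Watson statistic on residuals in
   input row order.

The Mann–Whitney Z deliberately uses the asymptotic form without continuity
correction, so that for two tie-free groups H = Z² exactly (the classical
equivalence of the two rank tests).  An exact-enumeration p-value is
available for very small samples via ``exact=True``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from .cohort import PREDICTOR_TOKENS, REFERENCE_TOKENS, SurveyRecord
from .descriptives import cohort_dimension_scores
from .errors import DomainError

# --------------------------------------------------------------------------
# Dummy coding layout
# --------------------------------------------------------------------------

#: factor name -> (non-reference dummy tokens, reference token)
FACTOR_DUMMIES: dict[str, tuple[tuple[str, ...], str]] = {
    "age_band": (("age_66_70", "age_71_80", "age_ge81"), "age_60_65"),
    "education": (("education_high",), "education_low"),
    "spouse": (("spouse_none",), "spouse_yes"),
    "children": (("children_ge2",), "children_le1"),
    "living_alone": (("living_alone",), "not_living_alone"),
    "self_care": (("disabled",), "independent"),
    "chronic": (("chronic",), "no_chronic"),
    "income_band": (("income_1501_3000", "income_3001_4999", "income_gt5000"), "income_0_1500"),
}

#: predictor token -> owning factor
TOKEN_FACTOR: dict[str, str] = {
    tok: fac for fac, (toks, _ref) in FACTOR_DUMMIES.items() for tok in toks
}


def design_matrix(cohort: Sequence[SurveyRecord], factors: Sequence[str]) -> pd.DataFrame:
    """0/1 dummy columns for the requested factors, reference levels dropped."""
    unknown = [f for f in factors if f not in FACTOR_DUMMIES]
    if unknown:
        raise DomainError(f"unknown factors: {unknown}")
    token_sets = [r.profile.predictor_tokens() for r in cohort]
    data = {}
    for fac in factors:
        for tok in FACTOR_DUMMIES[fac][0]:
            data[tok] = np.array([1.0 if tok in s else 0.0 for s in token_sets])
    return pd.DataFrame(data, index=[r.respondent_id for r in cohort])


# --------------------------------------------------------------------------
# Result types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    factor: str
    dimension: str
    statistic_kind: str  # "mann_whitney_z" | "kruskal_wallis_h"
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value {self.p_value!r} outside [0, 1]")
        if self.statistic_kind == "kruskal_wallis_h" and self.statistic < 0:
            raise DomainError("H statistic must be non-negative")


@dataclass(frozen=True)
class CoefficientRecord:
    """One predictor row of a per-dimension regression table."""

    dimension: str
    factor: str
    predictor: str
    B: float
    se: float | None = None
    beta: float | None = None
    t: float | None = None
    p: float | None = None
    tolerance: float | None = None
    vif: float | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.is_reference:
            if self.B != 0.0:
                raise DomainError("reference rows must have B = 0")
        else:
            if self.p is not None and not (0.0 <= self.p <= 1.0):
                raise DomainError(f"p {self.p!r} outside [0, 1]")
            if self.se is not None and self.se < 0:
                raise DomainError("standard error must be >= 0")

    def is_significant(self, alpha: float = 0.05) -> bool:
        return (not self.is_reference) and self.p is not None and self.p < alpha


@dataclass(frozen=True)
class CollinearityStat:
    predictor: str
    tolerance: float
    vif: float
    infinite: bool = False


@dataclass
class RegressionFit:
    dimension: str
    coefficients: list[CoefficientRecord]
    intercept: float
    durbin_watson: float
    n_used: int
    r_squared: float
    residuals: np.ndarray = field(repr=False, default=None)

    def coefficient(self, predictor: str) -> CoefficientRecord:
        for rec in self.coefficients:
            if rec.predictor == predictor:
                return rec
        raise DomainError(f"no coefficient for predictor {predictor!r}")


# --------------------------------------------------------------------------
# Rank tests
# --------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    r_a = float(ranks[: len(a)].sum())
    return r_a - len(a) * (len(a) + 1) / 2.0


def mann_whitney_z(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    factor: str = "",
    dimension: str = "",
    exact: bool = False,
) -> TestResult:
    """Two-group rank test; Z from the tie-corrected normal approximation.

    ``Z = (U_a − n_a·n_b/2) / σ`` with the tie-corrected σ and no continuity
    correction; p is two-sided.  With ``exact=True`` (pooled n ≤ 14) the
    p-value is instead computed by enumerating all group assignments — the
    statistic reported stays Z.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(np.concatenate([a, b])) / (n * (n - 1)))
    if var <= 0:  # all pooled values identical
        return TestResult(factor, dimension, "mann_whitney_z", 0.0, 1.0)
    z = (u - mu) / math.sqrt(var)
    if exact:
        p = _exact_u_p_value(a, b, u)
    else:
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return TestResult(factor, dimension, "mann_whitney_z", z, p)


def _exact_u_p_value(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n_a) group assignments."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    if n > 14:
        raise DomainError(f"exact enumeration limited to pooled n <= 14, got {n}")
    us = []
    idx = range(n)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    lo = float(np.mean(us <= u_obs + 1e-12))
    hi = float(np.mean(us >= u_obs - 1e-12))
    return min(1.0, 2.0 * min(lo, hi))


def h_statistic(groups: Sequence[Sequence[float]]) -> tuple[float, int]:
    """Tie-corrected Kruskal–Wallis H and total sample size (any k >= 2)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r_mean = float(ranks[start: start + a.size].mean())
        h += a.size * (r_mean - (n + 1) / 2.0) ** 2
        start += a.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # every pooled value identical
        return 0.0, n
    return h / correction, n


def kruskal_wallis_h(
    groups: Sequence[Sequence[float]], *, factor: str = "", dimension: str = ""
) -> TestResult:
    """K-group rank test (k >= 3) with chi-square p on k−1 df."""
    if len(groups) < 3:
        raise DomainError("kruskal_wallis_h requires >= 3 groups; use mann_whitney_z for two")
    h, _ = h_statistic(groups)
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return TestResult(factor, dimension, "kruskal_wallis_h", h, p)


def univariate_screen(
    cohort: Sequence[SurveyRecord], dimension: str, factors: Sequence[str] | None = None
) -> list[TestResult]:
    """Run the appropriate rank test of every factor against one dimension."""
    factors = list(factors) if factors is not None else list(FACTOR_DUMMIES)
    scores = cohort_dimension_scores(cohort, dimension)
    frame = design_matrix(cohort, factors)
    results = []
    for fac in factors:
        toks, _ref = FACTOR_DUMMIES[fac]
        if len(toks) == 1:
            mask = frame[toks[0]].to_numpy() == 1.0
            if mask.all() or (~mask).all():
                raise DomainError(f"factor {fac!r} has a single level in this cohort")
            results.append(
                mann_whitney_z(scores[~mask], scores[mask], factor=fac, dimension=dimension)
            )
        else:
            groups = []
            ref_mask = np.ones(len(scores), dtype=bool)
            for tok in toks:
                m = frame[tok].to_numpy() == 1.0
                ref_mask &= ~m
                groups.append(scores[m])
            groups.insert(0, scores[ref_mask])
            if any(g.size == 0 for g in groups):
                raise DomainError(f"factor {fac!r} has an empty level in this cohort")
            results.append(kruskal_wallis_h(groups, factor=fac, dimension=dimension))
    return results


def screen_candidates(tests: Sequence[TestResult], alpha: float = 0.05) -> list[str]:
    """Factors whose best (minimum) p-value is strictly below alpha."""
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    best: dict[str, float] = {}
    order: list[str] = []
    for t in tests:
        if t.factor not in best:
            order.append(t.factor)
        best[t.factor] = min(best.get(t.factor, 1.0), t.p_value)
    return [f for f in order if best[f] < alpha]


# --------------------------------------------------------------------------
# Enter-method regression and diagnostics
# --------------------------------------------------------------------------

def collinearity_diagnostics(
    design: pd.DataFrame, residuals: np.ndarray
) -> tuple[list[CollinearityStat], float]:
    """Tolerance/VIF from auxiliary regressions plus the Durbin–Watson statistic.

    VIF_j = 1 / (1 − R²_j) where R²_j regresses column j on the remaining
    columns (with intercept).  Perfect collinearity is reported as an
    infinite VIF with ``infinite=True`` rather than an exception.
    """
    x = design.to_numpy(dtype=float)
    n, k = x.shape
    stats_out: list[CollinearityStat] = []
    const = np.ones((n, 1))
    for j, name in enumerate(design.columns):
        others = np.hstack([const, np.delete(x, j, axis=1)])
        r2 = OLS(x[:, j], others).fit().rsquared if k > 1 else 0.0
        tol = 1.0 - r2
        if tol <= 1e-10:
            stats_out.append(CollinearityStat(name, 0.0, math.inf, infinite=True))
        else:
            stats_out.append(CollinearityStat(name, tol, 1.0 / tol))
    resid = np.asarray(residuals, dtype=float)
    dw = float(_sm_durbin_watson(resid)) if np.any(resid != 0) else float("nan")
    return stats_out, dw


def fit_enter_regression(
    cohort: Sequence[SurveyRecord],
    dimension: str,
    factors: Sequence[str],
    *,
    y: Sequence[float] | None = None,
) -> RegressionFit:
    """OLS of the dimension score on all listed factors entered at once.

    ``y`` overrides the response (e.g. latent pre-rounding scores from the
    generator); by default the observed dimension scores are used.  The fit
    emits one ``CoefficientRecord`` per non-reference dummy (B, SE,
    standardized beta, t, p, tolerance, VIF) plus a zero reference row per
    factor, matching conventional dummy-coded regression tables.
    """
    response = (
        np.asarray(y, dtype=float) if y is not None else cohort_dimension_scores(cohort, dimension)
    )
    if len(response) != len(cohort):
        raise DomainError("response length must match cohort size")
    frame = design_matrix(cohort, factors)
    n, k = frame.shape
    if n <= k + 1:
        raise DomainError(f"cohort size {n} too small for {k} dummy columns")

    x = frame.to_numpy(dtype=float)
    exog = np.hstack([np.ones((n, 1)), x])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        aux, _ = collinearity_diagnostics(frame, np.zeros(n))
        bad = [s.predictor for s in aux if s.infinite]
        raise DomainError(f"rank-deficient design; collinear columns: {bad or list(frame.columns)}")

    res = OLS(response, exog).fit()
    coll, dw = collinearity_diagnostics(frame, np.asarray(res.resid))
    coll_by_name = {s.predictor: s for s in coll}

    sy = float(np.std(response, ddof=1))
    records: list[CoefficientRecord] = []
    for j, name in enumerate(frame.columns, start=1):
        sx = float(np.std(x[:, j - 1], ddof=1))
        s = coll_by_name[name]
        records.append(
            CoefficientRecord(
                dimension=dimension,
                factor=TOKEN_FACTOR[name],
                predictor=name,
                B=float(res.params[j]),
                se=float(res.bse[j]),
                beta=float(res.params[j]) * sx / sy if sy > 0 else 0.0,
                t=float(res.tvalues[j]),
                p=float(res.pvalues[j]),
                tolerance=s.tolerance,
                vif=s.vif,
            )
        )
    for fac in factors:
        records.append(
            CoefficientRecord(
                dimension=dimension,
                factor=fac,
                predictor=FACTOR_DUMMIES[fac][1],
                B=0.0,
                is_reference=True,
            )
        )

    return RegressionFit(
        dimension=dimension,
        coefficients=records,
        intercept=float(res.params[0]),
        durbin_watson=dw,
        n_used=n,
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
    )


def fit_all_dimensions(
    cohort: Sequence[SurveyRecord],
    alpha: float = 0.05,
    factors: Sequence[str] | None = None,
) -> dict[str, RegressionFit]:
    """Screen-then-Enter pipeline for every demand dimension."""
    from .cohort import DIMENSIONS  # local import keeps module load order simple

    fits = {}
    for dim in DIMENSIONS:
        tests = univariate_screen(cohort, dim, factors)
        selected = screen_candidates(tests, alpha)
        if not selected:
            continue
        fits[dim] = fit_enter_regression(cohort, dim, selected)
    return fits


def coefficients_to_frame(records: Sequence[CoefficientRecord]) -> pd.DataFrame:
    """Flat coefficient table (one row per predictor) for CSV/JSON export."""
    return pd.DataFrame(
        [
            {
                "dimension": r.dimension, "factor": r.factor, "predictor": r.predictor,
                "B": r.B, "se": r.se, "beta": r.beta, "t": r.t, "p": r.p,
                "tolerance": r.tolerance, "vif": r.vif, "is_reference": int(r.is_reference),
            }
            for r in records
        ]
    )
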