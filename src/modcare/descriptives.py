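"""Descriptive demand statistics: dimension scores, score rates, P75 thresholds.

Conventions (stated because the upstream instrument leaves them open):

* A dimension score is the unweighted mean of its items, so it lives on the
  same 1–5 scale as the items.
* The *score rate* of a dimension is the cohort mean dimension score as a
  percentage of the scale maximum, ``100 * mean / 5``, reported to two
  decimals (half-away-from-zero).
* Percentiles use the (n+1)p positional rule with linear interpolation
  between order statistics, positions clamped to [1, n] — the default
  percentile convention of mainstream commercial survey-statistics software
  (numpy's ``method="weibull"``).  The rule name is recorded in
  ``ThresholdSet.provenance`` so an alternative rule is auditable.
* A module's activation threshold is the 75th percentile (P75) of the
  dimension-score distribution over the whole cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import DIMENSIONS, DIMENSION_ITEMS, SurveyRecord
from .errors import DomainError

PERCENTILE_RULE = "weibull[(n+1)p]"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (92.715 -> 92.72)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(math.copysign(float(d), x)) if x else float(d)


def percentile(values: Sequence[float], p: float) -> float:
    """(n+1)p percentile with linear interpolation, clamped to the sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("percentile of empty sample")
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"percentile level must be in [0, 1], got {p}")
    return float(np.percentile(arr, 100.0 * p, method="weibull"))


@dataclass(frozen=True)
class DimensionScore:
    dimension: str
    value: float

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise DomainError(f"unknown dimension {self.dimension!r}")
        if not (1.0 <= self.value <= 5.0):
            raise DomainError(f"dimension score {self.value!r} outside [1, 5]")


@dataclass(frozen=True)
class DescriptiveSummary:
    dimension: str
    median: float
    p25: float
    p75: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p25 <= self.median <= self.p75):
            raise DomainError("expected p25 <= median <= p75")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-module P75 activation thresholds with provenance."""

    thresholds: Mapping[str, float]
    provenance: str

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(DIMENSIONS):
            raise DomainError(
                f"thresholds must cover exactly the five modules, got {sorted(self.thresholds)}"
            )
        for k, v in self.thresholds.items():
            if not (1.0 <= v <= 5.0):
                raise DomainError(f"threshold for {k} outside [1, 5]: {v!r}")

    def __getitem__(self, module: str) -> float:
        return self.thresholds[module]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"thresholds": dict(self.thresholds), "provenance": self.provenance},
                       indent=2),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(thresholds=data["thresholds"], provenance=data.get("provenance", "unknown"))


def dimension_score(record: SurveyRecord, dimension: str) -> DimensionScore:
    """Unweighted mean of the dimension's items for one respondent."""
    items = record.dimension_items(dimension)  # raises DomainError if unknown
    return DimensionScore(dimension, sum(items) / len(items))


def cohort_dimension_scores(cohort: Sequence[SurveyRecord], dimension: str) -> np.ndarray:
    """Vector of per-respondent dimension scores (internal workhorse)."""
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    if dimension not in DIMENSION_ITEMS:
        raise DomainError(f"unknown dimension {dimension!r}")
    idx = list(DIMENSION_ITEMS[dimension])
    mat = np.asarray([r.items for r in cohort], dtype=float)
    return mat[:, idx].mean(axis=1)


def score_rate(cohort: Sequence[SurveyRecord], dimension: str) -> float:
    """Cohort demand for a dimension as % of scale maximum, 2 decimals."""
    scores = cohort_dimension_scores(cohort, dimension)
    return round_half_away(100.0 * float(scores.mean()) / 5.0)


def summarize_dimension(cohort: Sequence[SurveyRecord], dimension: str) -> DescriptiveSummary:
    """Median (P25, P75) of the dimension scores under the declared rule."""
    scores = cohort_dimension_scores(cohort, dimension)
    return DescriptiveSummary(
        dimension=dimension,
        median=percentile(scores, 0.50),
        p25=percentile(scores, 0.25),
        p75=percentile(scores, 0.75),
        n=len(cohort),
    )


def compute_thresholds(cohort: Sequence[SurveyRecord], cohort_id: str = "cohort") -> ThresholdSet:
    """P75 of every dimension's score distribution over the whole cohort."""
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    thresholds = {
        dim: percentile(cohort_dimension_scores(cohort, dim), 0.75) for dim in DIMENSIONS
    }
    return ThresholdSet(thresholds=thresholds, provenance=f"{cohort_id}:P75:{PERCENTILE_RULE}")


def sample_size_required(
    n_vars: int, multiplier_low: int = 5, multiplier_high: int = 10, attrition: float = 0.20
) -> tuple[int, int]:
    """Events-per-variable sample-size rule with an attrition allowance.

    The planned range is ``multiplier_low``–``multiplier_high`` respondents
    per instrument variable, inflated by ``attrition`` for anticipated
    invalid responses, each bound rounded up.
    """
    if n_vars < 1:
        raise DomainError(f"n_vars must be >= 1, got {n_vars}")
    if not (0.0 <= attrition < 1.0):
        raise DomainError(f"attrition must be in [0, 1), got {attrition}")
    if multiplier_low > multiplier_high:
        raise DomainError("multiplier_low must be <= multiplier_high")
    # round to 9 decimals before ceil so 114.00000000000001 -> 114
    low = math.ceil(round(n_vars * multiplier_low * (1.0 + attrition), 9))
    high = math.ceil(round(n_vars * multiplier_high * (1.0 + attrition), 9))
    return low, high


def response_rate(distributed: int, valid: int) -> float:
    """Valid-response rate in percent, two decimals."""
    if distributed <= 0:
        raise DomainError(f"distributed must be > 0, got {distributed}")
    if not (0 <= valid <= distributed):
        raise DomainError(f"valid must be in [0, distributed], got {valid}")
    return round_half_away(100.0 * valid / distributed)


def describe_cohort(cohort: Sequence[SurveyRecord]) -> dict[str, dict[str, float | int]]:
    """All-dimension summary: median/P25/P75/n plus score rate, JSON-friendly."""
    out: dict[str, dict[str, float | int]] = {}
    for dim in DIMENSIONS:
        s = summarize_dimension(cohort, dim)
        out[dim] = {
            "median": s.median, "p25": s.p25, "p75": s.p75, "n": s.n,
            "score_rate": score_rate(cohort, dim),
        }
    return out
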