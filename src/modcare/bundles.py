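"""Service-bundle engine: module activation, weighting, and priority tiers.

A person's customized bundle over the five service modules M_k is

    S_i = sum_k  alpha_k,i * beta_k,i * M_k

where alpha_k,i ∈ {0, 1} switches module k on when the person's dimension
demand score is at or above the cohort P75 threshold (equality activates),
and beta_k,i ≥ 0 expresses relative demand intensity as the sum of the
module's statistically significant unstandardized regression coefficients
(B values) over the categories the person possesses.  Reference categories
and non-significant predictors contribute zero.  The bundle is represented
as a weighted set of module identifiers rather than a scalar sum — modules
are unlike quantities, so the Σ is symbolic.

``weighting_factor`` accepts either a full demographic profile (categories
derived automatically; unstated attributes sit at their reference levels)
or an explicit predictor set, which bypasses profile matching so published
per-module sums can be reproduced verbatim.

Tier-1 priority recipients are those of advanced age (≥71 years), living
alone, or disabled — any one criterion suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .association import CoefficientRecord
from .cohort import (
    DIMENSIONS,
    PREDICTOR_TOKENS,
    REFERENCE_TOKENS,
    RespondentProfile,
    SurveyRecord,
)
from .descriptives import DimensionScore, ThresholdSet, dimension_score
from .errors import DomainError


@dataclass(frozen=True)
class ServiceModule:
    """One of the five core service modules and its component services."""

    key: str
    display_name: str
    components: tuple[str, ...]


MODULES: dict[str, ServiceModule] = {
    m.key: m
    for m in (
        ServiceModule(
            "life_assistance",
            "Life Assistance Module",
            ("Hygiene care", "Catering services", "Emergency maintenance",
             "Entrusted agency services"),
        ),
        ServiceModule(
            "medical_care",
            "Medical Care Module",
            ("Health management", "Preventive healthcare", "Diagnosis & treatment",
             "Emergency rescue", "Rehabilitation guidance"),
        ),
        ServiceModule(
            "spiritual_cultural",
            "Spiritual/Cultural Engagement Module",
            ("Spiritual comfort", "Leisure activities", "Self-actualization"),
        ),
        ServiceModule(
            "rights_protection",
            "Rights Protection Module",
            ("Legal consultation/aid", "Policy service promotion", "Conflict mediation"),
        ),
        ServiceModule(
            "age_friendly",
            "Age-Friendly Modifications Module",
            ("Indoor modifications", "Public environment modifications"),
        ),
    )
}

assert tuple(MODULES) == DIMENSIONS

_KNOWN_TOKENS = frozenset(PREDICTOR_TOKENS) | frozenset(REFERENCE_TOKENS)


@dataclass(frozen=True)
class ActivationRule:
    module: str
    threshold: float

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise DomainError(f"unknown module {self.module!r}")
        if not (1.0 <= self.threshold <= 5.0):
            raise DomainError(f"threshold {self.threshold!r} outside [1, 5]")


@dataclass(frozen=True)
class ModuleAssignment:
    alpha: int  # 0 or 1
    beta: float
    contributing: tuple[tuple[str, float], ...]  # (predictor, B) pairs


@dataclass(frozen=True)
class ServiceBundle:
    respondent_id: int | str
    assignments: Mapping[str, ModuleAssignment]

    @property
    def included_modules(self) -> dict[str, float]:
        """Activated modules mapped to their weights (alpha * beta)."""
        return {k: a.beta for k, a in self.assignments.items() if a.alpha == 1}

    def alphas(self) -> tuple[int, ...]:
        return tuple(self.assignments[d].alpha for d in DIMENSIONS)


@dataclass(frozen=True)
class TierLevel:
    respondent_id: int | str | None
    tier: str  # "tier1" | "standard"
    triggers: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.tier == "tier1") != bool(self.triggers):
            raise DomainError("tier1 iff triggering attributes are non-empty")


def activation_coefficient(score: DimensionScore, rule: ActivationRule) -> int:
    """1 if the demand score meets or exceeds the threshold, else 0."""
    if score.dimension != rule.module:
        raise DomainError(
            f"score dimension {score.dimension!r} does not match module {rule.module!r}"
        )
    return 1 if score.value >= rule.threshold else 0


def weighting_factor(
    subject: RespondentProfile | Iterable[str],
    coefficients: Sequence[CoefficientRecord],
    module: str,
    alpha_sig: float = 0.05,
) -> tuple[float, tuple[tuple[str, float], ...]]:
    """Sum of significant B values possessed by the subject for one module.

    Returns ``(beta, contributing)`` where ``contributing`` lists the
    (predictor, B) pairs that entered the sum.
    """
    if module not in MODULES:
        raise DomainError(f"unknown module {module!r}")
    if isinstance(subject, RespondentProfile):
        tokens = subject.predictor_tokens()
    else:
        tokens = frozenset(subject)
        unknown = tokens - _KNOWN_TOKENS
        if unknown:
            raise DomainError(f"unknown predictor categories: {sorted(unknown)}")
    rows = [r for r in coefficients if r.dimension == module]
    if not rows:
        raise DomainError(f"coefficient table has no rows for module {module!r}")
    contributing = tuple(
        (r.predictor, r.B)
        for r in rows
        if r.is_significant(alpha_sig) and r.predictor in tokens
    )
    return sum(b for _, b in contributing), contributing


def build_bundle(
    record: SurveyRecord | Mapping[str, float],
    thresholds: ThresholdSet,
    coefficients: Sequence[CoefficientRecord],
    *,
    profile: RespondentProfile | None = None,
    strict_sets: Mapping[str, Iterable[str]] | None = None,
    alpha_sig: float = 0.05,
    respondent_id: int | str | None = None,
) -> ServiceBundle:
    """Assemble one person's service bundle.

    ``record`` is either a full survey record (dimension scores computed
    from its items, weights from its profile) or a mapping of dimension
    demand scores — in that case supply ``profile`` or ``strict_sets``.
    ``strict_sets`` maps module keys to explicit predictor sets and takes
    precedence over the profile; modules absent from it get beta 0.
    Modules whose score falls below threshold are carried with alpha 0 and
    no weight.
    """
    if isinstance(record, SurveyRecord):
        scores = {d: dimension_score(record, d) for d in DIMENSIONS}
        subject_profile = record.profile if profile is None else profile
        rid = record.respondent_id if respondent_id is None else respondent_id
    else:
        missing = set(DIMENSIONS) - set(record)
        if missing:
            raise DomainError(f"missing dimension scores: {sorted(missing)}")
        scores = {d: DimensionScore(d, float(record[d])) for d in DIMENSIONS}
        subject_profile = profile
        rid = respondent_id
        if subject_profile is None and strict_sets is None:
            raise DomainError("score-mapping input needs a profile or strict_sets")

    assignments: dict[str, ModuleAssignment] = {}
    for module in DIMENSIONS:
        alpha = activation_coefficient(
            scores[module], ActivationRule(module, thresholds[module])
        )
        if alpha == 0:
            assignments[module] = ModuleAssignment(0, 0.0, ())
            continue
        if strict_sets is not None:
            subject: RespondentProfile | Iterable[str] = frozenset(strict_sets.get(module, ()))
        else:
            subject = subject_profile
        beta, contributing = weighting_factor(subject, coefficients, module, alpha_sig)
        assignments[module] = ModuleAssignment(1, beta, contributing)
    return ServiceBundle(respondent_id=rid, assignments=assignments)


def classify_tier(
    profile: RespondentProfile, respondent_id: int | str | None = None
) -> TierLevel:
    """Tier-1 priority: advanced age (≥71), living alone, or disabled."""
    triggers = []
    if profile.age_band in ("71-80", ">=81"):
        triggers.append("advanced_age")
    if profile.living_alone:
        triggers.append("living_alone")
    if profile.disabled:
        triggers.append("disabled")
    tier = "tier1" if triggers else "standard"
    return TierLevel(respondent_id=respondent_id, tier=tier, triggers=tuple(triggers))


def bundle_to_dict(bundle: ServiceBundle, tier: TierLevel | None = None) -> dict:
    """JSON-friendly view of one bundle (plus tier if provided)."""
    out = {
        "respondent_id": bundle.respondent_id,
        "modules": {
            k: {
                "alpha": a.alpha,
                "beta": a.beta,
                "contributing": [{"predictor": p, "B": b} for p, b in a.contributing],
            }
            for k, a in bundle.assignments.items()
        },
    }
    if tier is not None:
        out["tier"] = tier.tier
        out["tier_triggers"] = list(tier.triggers)
    return out
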