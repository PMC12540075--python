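"""Synthetic survey cohorts for community home-based older adult care demand.

The demand instrument has five dimensions covered by 19 items, each rated on
a 5-point Likert scale (1 = not needed at all ... 5 = strongly needed):

=======================  =====  ==========================================
dimension                items  content
=======================  =====  ==========================================
life_assistance          5      hygiene care, mobility, catering, agency
                                services, emergency maintenance
medical_care             6      health management, preventive care,
                                diagnosis & treatment, rehabilitation,
                                nursing, emergency rescue
spiritual_cultural       3      spiritual comfort, leisure, self-actualization
rights_protection        3      mediation, legal aid, policy promotion
age_friendly             2      indoor and public environment modifications
=======================  =====  ==========================================

A respondent is a bundle of demographic categories (age band, education,
spouse, children, living arrangement, self-care ability, chronic disease,
income band) plus the 19 item scores.  The generator draws demographic
factors independently from configured marginal prevalences (the packaged
defaults reproduce the study sample's marginals, e.g. 17.22% living alone,
19.64% disabled, 71.00% with chronic disease), then simulates item scores
from a latent-score model: each dimension has a latent score

    latent = intercept + sum(effect of each non-reference category) + noise

with Gaussian noise of standard deviation ``noise_sd``; every item in the
dimension adds independent per-item Gaussian noise of the same sd on top of
the shared dimension latent, and the item response is the latent rounded
half-away-from-zero and clamped to [1, 5].  Sharing the dimension latent
makes dimension means less noisy than single items, mirroring a multi-item
instrument.  Because the true effects are known, the generator supports
parameter-recovery testing of the downstream regression.

Reproducibility: a single integer master seed; respondent ``i`` draws its
profile from substream ``(seed, i, 0)`` and its item scores from
``(seed, i, 1)``, so cohorts are stable under partial regeneration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

# --------------------------------------------------------------------------
# Instrument layout
# --------------------------------------------------------------------------

DIMENSIONS: tuple[str, ...] = (
    "life_assistance",
    "medical_care",
    "spiritual_cultural",
    "rights_protection",
    "age_friendly",
)

#: 0-based item index ranges per dimension (items are stored in this order).
DIMENSION_ITEMS: dict[str, range] = {
    "life_assistance": range(0, 5),
    "medical_care": range(5, 11),
    "spiritual_cultural": range(11, 14),
    "rights_protection": range(14, 17),
    "age_friendly": range(17, 19),
}

N_ITEMS = 19
SCALE_MIN, SCALE_MAX = 1, 5

AGE_BANDS: tuple[str, ...] = ("60-65", "66-70", "71-80", ">=81")
INCOME_BANDS: tuple[str, ...] = ("0-1500", "1501-3000", "3001-4999", ">5000")

# Dummy-coding tokens for non-reference categories, used both by the
# generator truth and by the regression/bundling layers.
AGE_TOKENS = {"66-70": "age_66_70", "71-80": "age_71_80", ">=81": "age_ge81"}
INCOME_TOKENS = {
    "1501-3000": "income_1501_3000",
    "3001-4999": "income_3001_4999",
    ">5000": "income_gt5000",
}

#: All recognised non-reference predictor tokens.
PREDICTOR_TOKENS: tuple[str, ...] = (
    "age_66_70",
    "age_71_80",
    "age_ge81",
    "education_high",
    "spouse_none",
    "children_ge2",
    "living_alone",
    "disabled",
    "chronic",
    "income_1501_3000",
    "income_3001_4999",
    "income_gt5000",
)

#: Reference (baseline) category tokens; they always contribute zero effect.
REFERENCE_TOKENS: tuple[str, ...] = (
    "age_60_65",
    "education_low",
    "spouse_yes",
    "children_le1",
    "not_living_alone",
    "independent",
    "no_chronic",
    "income_0_1500",
)


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def clamp_item(latent: float) -> int:
    """Map a latent value to the 1–5 Likert response."""
    return min(SCALE_MAX, max(SCALE_MIN, _round_half_away(latent)))


# --------------------------------------------------------------------------
# Configuration and domain types
# --------------------------------------------------------------------------

def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {p!r}")


def _check_simplex(name: str, probs: Sequence[float], size: int) -> None:
    if len(probs) != size:
        raise ConfigurationError(f"{name} must have {size} entries, got {len(probs)}")
    for p in probs:
        _check_prob(name, p)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1 within 1e-9, got {sum(probs)!r}")


# Study-sample marginal prevalences (fractions of the n=331 survey sample).
STUDY_MARGINALS = {
    "age_band_probs": (0.3263, 0.2236, 0.3323, 0.1178),
    "p_high_education": 0.2447,
    "p_no_spouse": 0.2840,
    "p_two_plus_children": 0.5257,
    "p_living_alone": 0.1722,
    "p_disabled": 0.1964,
    "p_chronic": 0.7100,
    "income_band_probs": (0.0846, 0.4169, 0.3414, 0.1571),
}


@dataclass(frozen=True)
class DemographicConfig:
    """Marginal prevalences of the demographic factors plus cohort size/seed.

    Factors are drawn independently by default.  ``p_living_alone_by_spouse``
    optionally replaces the marginal living-alone prevalence with a pair
    ``(p_given_spouse, p_given_no_spouse)`` to induce the obvious joint
    structure between widowhood and solitary living; it is off by default
    because only marginals are known for the study sample.
    """

    n: int = 331
    seed: int = 0
    age_band_probs: tuple[float, float, float, float] = STUDY_MARGINALS["age_band_probs"]
    p_high_education: float = STUDY_MARGINALS["p_high_education"]
    p_no_spouse: float = STUDY_MARGINALS["p_no_spouse"]
    p_two_plus_children: float = STUDY_MARGINALS["p_two_plus_children"]
    p_living_alone: float = STUDY_MARGINALS["p_living_alone"]
    p_disabled: float = STUDY_MARGINALS["p_disabled"]
    p_chronic: float = STUDY_MARGINALS["p_chronic"]
    income_band_probs: tuple[float, float, float, float] = STUDY_MARGINALS["income_band_probs"]
    p_living_alone_by_spouse: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")
        _check_simplex("age_band_probs", self.age_band_probs, 4)
        _check_simplex("income_band_probs", self.income_band_probs, 4)
        for name in ("p_high_education", "p_no_spouse", "p_two_plus_children",
                     "p_living_alone", "p_disabled", "p_chronic"):
            _check_prob(name, getattr(self, name))
        if self.p_living_alone_by_spouse is not None:
            for p in self.p_living_alone_by_spouse:
                _check_prob("p_living_alone_by_spouse", p)


@dataclass(frozen=True)
class RespondentProfile:
    """One respondent's demographic categories."""

    age_band: str
    education: str  # "low" | "high"
    spouse: str  # "yes" | "none"
    children: str  # "<=1" | ">=2"
    living_alone: bool
    disabled: bool
    chronic: bool
    income_band: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ConfigurationError(f"unknown age band {self.age_band!r}")
        if self.education not in ("low", "high"):
            raise ConfigurationError(f"unknown education {self.education!r}")
        if self.spouse not in ("yes", "none"):
            raise ConfigurationError(f"unknown spouse status {self.spouse!r}")
        if self.children not in ("<=1", ">=2"):
            raise ConfigurationError(f"unknown children group {self.children!r}")
        if self.income_band not in INCOME_BANDS:
            raise ConfigurationError(f"unknown income band {self.income_band!r}")

    def predictor_tokens(self) -> frozenset[str]:
        """Non-reference dummy categories this respondent possesses."""
        tokens: list[str] = []
        if self.age_band in AGE_TOKENS:
            tokens.append(AGE_TOKENS[self.age_band])
        if self.education == "high":
            tokens.append("education_high")
        if self.spouse == "none":
            tokens.append("spouse_none")
        if self.children == ">=2":
            tokens.append("children_ge2")
        if self.living_alone:
            tokens.append("living_alone")
        if self.disabled:
            tokens.append("disabled")
        if self.chronic:
            tokens.append("chronic")
        if self.income_band in INCOME_TOKENS:
            tokens.append(INCOME_TOKENS[self.income_band])
        return frozenset(tokens)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth latent-score model: per-dimension intercepts and effects.

    ``effects[dimension]`` maps predictor tokens (see ``PREDICTOR_TOKENS``)
    to additive shifts, in score units on the 1–5 scale, applied when the
    respondent possesses the category.  ``noise_sd`` is the standard
    deviation (score units) of both the shared dimension noise and the
    per-item noise.
    """

    intercepts: Mapping[str, float]
    effects: Mapping[str, Mapping[str, float]]
    noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        missing = [d for d in DIMENSIONS if d not in self.intercepts]
        if missing:
            raise ConfigurationError(f"truth missing intercepts for dimensions: {missing}")
        for dim, eff in self.effects.items():
            if dim not in DIMENSIONS:
                raise ConfigurationError(f"unknown dimension {dim!r} in truth")
            unknown = set(eff) - set(PREDICTOR_TOKENS)
            if unknown:
                raise ConfigurationError(f"unknown predictor tokens in truth: {sorted(unknown)}")

    @classmethod
    def null(cls, intercept: float = 3.0, noise_sd: float = 0.6) -> "GeneratorTruth":
        """A no-effect model: every dimension latent is intercept + noise."""
        return cls(
            intercepts={d: intercept for d in DIMENSIONS},
            effects={d: {} for d in DIMENSIONS},
            noise_sd=noise_sd,
        )

    def dimension_mean(self, profile: RespondentProfile, dimension: str) -> float:
        """Noise-free latent mean for one respondent and dimension."""
        eff = self.effects.get(dimension, {})
        tokens = profile.predictor_tokens()
        return self.intercepts[dimension] + sum(b for t, b in eff.items() if t in tokens)


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent: profile + the 19 item scores (+ latent scores if kept)."""

    respondent_id: int
    profile: RespondentProfile
    items: tuple[int, ...]
    #: noise-free-of-items latent dimension scores (pre-rounding), kept when
    #: generated so parameter recovery can regress on the latent scale;
    #: not serialised to CSV.
    latents: tuple[float, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ConfigurationError(f"expected {N_ITEMS} items, got {len(self.items)}")
        for v in self.items:
            if not (SCALE_MIN <= v <= SCALE_MAX):
                raise ConfigurationError(f"item score {v!r} outside [1, 5]")

    def dimension_items(self, dimension: str) -> tuple[int, ...]:
        if dimension not in DIMENSION_ITEMS:
            raise DomainError(f"unknown dimension {dimension!r}")
        return tuple(self.items[i] for i in DIMENSION_ITEMS[dimension])


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def _draw_category(u: float, probs: Sequence[float], labels: Sequence[str]) -> str:
    acc = 0.0
    for p, lab in zip(probs, labels):
        acc += p
        if u < acc:
            return lab
    return labels[-1]


def _profile_from_uniforms(u: np.ndarray, config: DemographicConfig) -> RespondentProfile:
    spouse = "none" if u[2] < config.p_no_spouse else "yes"
    if config.p_living_alone_by_spouse is not None:
        p_alone = config.p_living_alone_by_spouse[1 if spouse == "none" else 0]
    else:
        p_alone = config.p_living_alone
    return RespondentProfile(
        age_band=_draw_category(u[0], config.age_band_probs, AGE_BANDS),
        education="high" if u[1] < config.p_high_education else "low",
        spouse=spouse,
        children=">=2" if u[3] < config.p_two_plus_children else "<=1",
        living_alone=bool(u[4] < p_alone),
        disabled=bool(u[5] < config.p_disabled),
        chronic=bool(u[6] < config.p_chronic),
        income_band=_draw_category(u[7], config.income_band_probs, INCOME_BANDS),
    )


def sample_profiles(config: DemographicConfig) -> list[RespondentProfile]:
    """Draw ``config.n`` independent respondent profiles.

    Each factor is drawn independently from its marginal prevalence; the
    draw for respondent ``i`` comes from substream ``(seed, i, 0)`` so the
    same seed always reproduces the same profiles.
    """
    out = []
    for i in range(config.n):
        rng = np.random.default_rng((config.seed, i, 0))
        out.append(_profile_from_uniforms(rng.random(8), config))
    return out


def _simulate_items(
    profile: RespondentProfile, truth: GeneratorTruth, rng: np.random.Generator
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    items: list[int] = []
    latents: list[float] = []
    sd = truth.noise_sd
    for dim in DIMENSIONS:
        k = len(DIMENSION_ITEMS[dim])
        z = rng.standard_normal(1 + k)
        latent = truth.dimension_mean(profile, dim) + sd * z[0]
        latents.append(latent)
        items.extend(clamp_item(latent + sd * zj) for zj in z[1:])
    return tuple(items), tuple(latents)


def simulate_item_scores(
    profile: RespondentProfile, truth: GeneratorTruth, seed: int
) -> tuple[int, ...]:
    """Simulate one respondent's 19 item scores from the latent model.

    With ``noise_sd=0`` the result is a deterministic function of the
    profile: every item equals the clamped, rounded dimension mean.
    """
    items, _ = _simulate_items(profile, truth, np.random.default_rng(seed))
    return items


def generate_cohort(
    config: DemographicConfig, truth: GeneratorTruth
) -> list[SurveyRecord]:
    """Generate a full cohort of survey records (deterministic per seed).

    Records carry the pre-rounding latent dimension scores in ``latents``
    so the latent scale remains available for parameter-recovery analyses.
    """
    records = []
    for i in range(config.n):
        rng_p = np.random.default_rng((config.seed, i, 0))
        profile = _profile_from_uniforms(rng_p.random(8), config)
        rng_s = np.random.default_rng((config.seed, i, 1))
        items, latents = _simulate_items(profile, truth, rng_s)
        records.append(SurveyRecord(i + 1, profile, items, latents))
    return records


# --------------------------------------------------------------------------
# CSV interface
# --------------------------------------------------------------------------

CSV_COLUMNS = (
    "respondent_id", "age_band", "education", "spouse", "children",
    "living_alone", "disabled", "chronic", "income_band",
    *(f"item_{i:02d}" for i in range(1, N_ITEMS + 1)),
)


def write_cohort_csv(records: Iterable[SurveyRecord], path: str | Path) -> None:
    path = Path(path)
    try:
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_COLUMNS)
            for r in records:
                p = r.profile
                w.writerow([
                    r.respondent_id, p.age_band, p.education, p.spouse, p.children,
                    int(p.living_alone), int(p.disabled), int(p.chronic), p.income_band,
                    *r.items,
                ])
    except OSError as exc:
        raise OSError(f"failed to write cohort CSV to {path}: {exc}") from exc


def read_cohort_csv(path: str | Path) -> list[SurveyRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DomainError(f"cohort CSV {path} missing columns: {sorted(missing)}")
        for row in reader:
            profile = RespondentProfile(
                age_band=row["age_band"],
                education=row["education"],
                spouse=row["spouse"],
                children=row["children"],
                living_alone=bool(int(row["living_alone"])),
                disabled=bool(int(row["disabled"])),
                chronic=bool(int(row["chronic"])),
                income_band=row["income_band"],
            )
            items = tuple(int(row[f"item_{i:02d}"]) for i in range(1, N_ITEMS + 1))
            records.append(SurveyRecord(int(row["respondent_id"]), profile, items))
    return records
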