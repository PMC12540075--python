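"""Packaged study reference data.

This module exposes, as plain Python objects, the published empirical
anchors the pipeline consumes when no freshly surveyed cohort is available:

* the full per-dimension regression coefficient table (B, SE, beta, t, p,
  tolerance, VIF) transcribed from the study's multivariable analysis of
  its 331-respondent survey;
* the per-module P75 activation thresholds of that sample;
* the published worked example ("Grandmother Zhang": an 82-year-old widowed
  woman, living alone, disabled, with chronic disease) with her dimension
  demand scores and the explicit predictor sets her bundle was built from.

Notes on transcription: p-values printed as "0.000" are stored as 0.0
(i.e. below printed precision), and tolerance/VIF columns carry the printed
3-decimal rounding, so ``tolerance * vif`` is 1 only to about 1e-3 here
(freshly computed tables satisfy it to machine precision).
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .association import CoefficientRecord
from .cohort import DIMENSIONS, GeneratorTruth
from .descriptives import ThresholdSet


def _load_rows() -> list[dict[str, str]]:
    with resources.files("modcare.data").joinpath("coefficients.csv").open(
        newline="", encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh))


def _maybe_float(s: str) -> float | None:
    return float(s) if s not in ("", None) else None


def study_coefficients() -> list[CoefficientRecord]:
    """The packaged coefficient table as CoefficientRecord rows (no constants)."""
    records = []
    for row in _load_rows():
        if row["factor"] == "constant":
            continue
        is_ref = row["is_reference"] == "1"
        records.append(
            CoefficientRecord(
                dimension=row["dimension"],
                factor=row["factor"],
                predictor=row["predictor"],
                B=float(row["B"]),
                se=None if is_ref else _maybe_float(row["se"]),
                beta=None if is_ref else _maybe_float(row["beta"]),
                t=None if is_ref else _maybe_float(row["t"]),
                p=None if is_ref else _maybe_float(row["p"]),
                tolerance=None if is_ref else _maybe_float(row["tolerance"]),
                vif=None if is_ref else _maybe_float(row["vif"]),
                is_reference=is_ref,
            )
        )
    return records


def study_intercepts() -> dict[str, float]:
    """Per-dimension regression constants."""
    return {
        row["dimension"]: float(row["B"])
        for row in _load_rows()
        if row["factor"] == "constant"
    }


def study_truth(noise_sd: float = 0.6) -> GeneratorTruth:
    """Generator ground truth using every published B (significant or not)."""
    effects: dict[str, dict[str, float]] = {d: {} for d in DIMENSIONS}
    for rec in study_coefficients():
        if not rec.is_reference:
            effects[rec.dimension][rec.predictor] = rec.B
    return GeneratorTruth(intercepts=study_intercepts(), effects=effects, noise_sd=noise_sd)


#: Per-module P75 activation thresholds of the study sample (upper quartile
#: of each dimension's score distribution over all 331 respondents).
STUDY_THRESHOLDS = ThresholdSet(
    thresholds={
        "life_assistance": 3.80,
        "medical_care": 3.83,
        "spiritual_cultural": 4.00,
        "rights_protection": 4.00,
        "age_friendly": 4.00,
    },
    provenance="study-sample-n331:P75",
)

#: Worked example: dimension demand scores assessed for Grandmother Zhang.
ZHANG_SCORES = {
    "life_assistance": 4.2,
    "medical_care": 4.2,
    "spiritual_cultural": 3.5,
    "rights_protection": 3.5,
    "age_friendly": 4.0,
}

#: Worked example: the explicit predictor sets the published bundle sums
#: over (per activated module).  They differ from Zhang's full profile in
#: one place — chronic disease is omitted from the life-assistance sum.
ZHANG_PREDICTOR_SETS = {
    "life_assistance": frozenset({"age_ge81", "spouse_none", "living_alone", "disabled"}),
    "medical_care": frozenset({"spouse_none", "living_alone", "disabled", "chronic"}),
    "age_friendly": frozenset({"spouse_none", "disabled"}),
}


def zhang_profile():
    """Grandmother Zhang's full demographic profile (unstated fields at reference)."""
    from .cohort import RespondentProfile

    return RespondentProfile(
        age_band=">=81",
        education="low",
        spouse="none",
        children="<=1",
        living_alone=True,
        disabled=True,
        chronic=True,
        income_band="0-1500",
    )
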