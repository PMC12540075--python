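"""Demand-Service Matching Index (DSMI) monitoring and recombination loop.

    DSMI = (actual service coverage rate / expected demand coverage rate)
           × service satisfaction

All three operands are fractions: coverage rates are delivered/planned
service units over the activated modules, and satisfaction is the mean
5-point satisfaction rating divided by 5.  DSMI may exceed 1 (over-delivery
with high satisfaction) and is deliberately not clamped — the feedback rule
only concerns the low side: a value at or below the trigger threshold
(default 0.8) flags a supply–demand mismatch and triggers module
recombination, i.e. re-running the bundle engine with refreshed scores,
thresholds or weights.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .bundles import ServiceBundle
from .errors import DomainError

DEFAULT_TRIGGER_THRESHOLD = 0.8


@dataclass(frozen=True)
class ServiceDeliveryRecord:
    respondent_id: int | str
    period: int
    actual_coverage: float
    expected_coverage: float
    satisfaction: float

    def __post_init__(self) -> None:
        for name in ("actual_coverage", "expected_coverage", "satisfaction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must be in [0, 1], got {v!r}")
        if self.expected_coverage <= 0.0:
            raise DomainError("expected_coverage must be > 0")


@dataclass(frozen=True)
class DSMIRecord:
    respondent_id: int | str
    period: int
    dsmi: float
    triggered: bool

    def __post_init__(self) -> None:
        if self.dsmi < 0:
            raise DomainError("DSMI must be >= 0")


@dataclass(frozen=True)
class MonitorDecision:
    action: str  # "keep" | "recombine"
    bundle: ServiceBundle  # final (possibly revised) bundle
    iterations: int  # periods processed
    unresolved: bool = False  # trigger persisted at the iteration cap


def compute_dsmi(
    record: ServiceDeliveryRecord, threshold: float = DEFAULT_TRIGGER_THRESHOLD
) -> DSMIRecord:
    """DSMI for one monitoring observation, with its trigger flag."""
    dsmi = (record.actual_coverage / record.expected_coverage) * record.satisfaction
    return DSMIRecord(
        respondent_id=record.respondent_id,
        period=record.period,
        dsmi=dsmi,
        triggered=evaluate_trigger(dsmi, threshold),
    )


def evaluate_trigger(dsmi: float, threshold: float = DEFAULT_TRIGGER_THRESHOLD) -> bool:
    """True iff the index has fallen to or below the threshold."""
    return dsmi <= threshold


def run_monitor_cycle(
    bundle: ServiceBundle,
    delivery_stream: Sequence[ServiceDeliveryRecord],
    rebundle: Callable[[ServiceBundle, ServiceDeliveryRecord], ServiceBundle],
    max_iter: int,
    threshold: float = DEFAULT_TRIGGER_THRESHOLD,
) -> tuple[MonitorDecision, list[DSMIRecord]]:
    """Monitor a delivery stream, recombining the bundle on every trigger.

    Processes at most ``max_iter`` periods in stream order.  Each period's
    DSMI is computed and appended to the history; a triggered period calls
    the ``rebundle`` hook to revise the activated modules or their weights,
    after which monitoring continues.  If the cap is reached while the
    latest period still triggers, the decision is flagged ``unresolved``.
    """
    if max_iter < 1:
        raise DomainError(f"max_iter must be >= 1, got {max_iter}")
    history: list[DSMIRecord] = []
    current = bundle
    recombined = False
    for delivery in delivery_stream[:max_iter]:
        rec = compute_dsmi(delivery, threshold)
        history.append(rec)
        if rec.triggered:
            recombined = True
            current = rebundle(current, delivery)
    unresolved = (
        len(delivery_stream) > max_iter and bool(history) and history[-1].triggered
    )
    action = "recombine" if recombined else "keep"
    return MonitorDecision(action, current, len(history), unresolved), history


# --------------------------------------------------------------------------
# File interfaces
# --------------------------------------------------------------------------

DELIVERY_COLUMNS = ("respondent_id", "period", "actual_coverage", "expected_coverage",
                    "satisfaction")


def read_delivery_csv(path: str | Path) -> list[ServiceDeliveryRecord]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(DELIVERY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DomainError(f"delivery CSV missing columns: {sorted(missing)}")
        return [
            ServiceDeliveryRecord(
                respondent_id=row["respondent_id"],
                period=int(row["period"]),
                actual_coverage=float(row["actual_coverage"]),
                expected_coverage=float(row["expected_coverage"]),
                satisfaction=float(row["satisfaction"]),
            )
            for row in reader
        ]


def write_history_csv(history: Sequence[DSMIRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("respondent_id", "period", "dsmi", "triggered"))
        for rec in history:
            w.writerow((rec.respondent_id, rec.period, rec.dsmi, int(rec.triggered)))


def write_decision_json(decision: MonitorDecision, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "action": decision.action,
                "iterations": decision.iterations,
                "unresolved": decision.unresolved,
                "respondent_id": decision.bundle.respondent_id,
                "included_modules": decision.bundle.included_modules,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
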