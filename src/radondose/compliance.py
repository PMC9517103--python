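"""Regulatory decision workflow and compliance reporting.

Implements the workplace radon-protection decision chain: screen for radon
potential (occupancy over 50 h/year at a flagged location), measure, branch
on the 300 Bq/m³ reference level, attempt constructive mitigation, and fall
back to operational mitigation — the dose-surveillance regime the planner
implements — when building works cannot bring the concentration down.

Boundary convention: the reference level is a maximum, so a concentration
exactly at it does NOT trigger mitigation; only strictly greater does.
Whether further constructive attempts are reasonable is a human judgment
supplied as a boolean, never inferred.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from . import dose_model
from .dose_model import DoseParameters, WorkerCategory
from .errors import StateMachineError
from .registry import Ledger, WorkerRegistry, Worksite


@dataclass(frozen=True)
class PotentialVerdict:
    """Outcome of the radon-potential screen for one worksite."""

    has_potential: bool
    triggered_criteria: tuple[str, ...]
    occupancy_ok: bool


def check_radon_potential(site: Worksite, params: DoseParameters) -> PotentialVerdict:
    """Screen a worksite for radon potential.

    Potential exists iff the workplace is occupied strictly more than
    ``params.potential_occupancy_threshold`` hours a year AND at least one
    location criterion applies (radon-prone area, underground, thermal or
    underground-water facility, previously detected high levels, nationally
    listed workplace type).
    """
    occupancy_ok = site.occupancy_hours_per_year > params.potential_occupancy_threshold
    criteria = tuple(site.location_flags.true_flags())
    return PotentialVerdict(
        has_potential=occupancy_ok and bool(criteria),
        triggered_criteria=criteria,
        occupancy_ok=occupancy_ok,
    )


class WorkflowState(enum.Enum):
    NO_POTENTIAL = "NO_POTENTIAL"
    MEASURE = "MEASURE"
    PERIODIC_REMEASURE = "PERIODIC_REMEASURE"
    MITIGATE = "MITIGATE"
    OPERATIONAL_MITIGATION = "OPERATIONAL_MITIGATION"


def initial_workflow_state(site: Worksite, params: DoseParameters) -> WorkflowState:
    """Entry point of the workflow: MEASURE if there is potential, else done."""
    verdict = check_radon_potential(site, params)
    return WorkflowState.MEASURE if verdict.has_potential else WorkflowState.NO_POTENTIAL


def next_workflow_state(
    current: WorkflowState,
    measured_concentration: float | None = None,
    mitigation_feasible: bool | None = None,
    params: DoseParameters = DoseParameters(),
) -> WorkflowState:
    """Advance the workflow one step.

    Legal transitions:

    * MEASURE + concentration > reference level → MITIGATE
    * MEASURE + concentration ≤ reference level → PERIODIC_REMEASURE
    * MITIGATE + post-works concentration ≤ reference level → PERIODIC_REMEASURE
    * MITIGATE + still above, further works feasible → MITIGATE (try again)
    * MITIGATE + still above, not feasible → OPERATIONAL_MITIGATION

    Any other (state, input) combination raises
    :class:`~radondose.errors.StateMachineError` naming the current state
    and offending input.
    """
    if current in (
        WorkflowState.NO_POTENTIAL,
        WorkflowState.PERIODIC_REMEASURE,
        WorkflowState.OPERATIONAL_MITIGATION,
    ):
        raise StateMachineError(
            f"state {current.value} accepts no transition input "
            f"(got concentration={measured_concentration}, "
            f"mitigation_feasible={mitigation_feasible})"
        )
    if measured_concentration is None:
        raise StateMachineError(
            f"state {current.value} requires a measured concentration"
        )
    if measured_concentration < 0:
        raise StateMachineError(
            f"measured concentration must be >= 0 Bq/m³, got {measured_concentration}"
        )

    above = measured_concentration > params.reference_level
    if current is WorkflowState.MEASURE:
        if mitigation_feasible is not None:
            raise StateMachineError(
                "mitigation_feasible is only meaningful from MITIGATE, "
                f"not {current.value}"
            )
        return WorkflowState.MITIGATE if above else WorkflowState.PERIODIC_REMEASURE
    # current is MITIGATE
    if not above:
        return WorkflowState.PERIODIC_REMEASURE
    if mitigation_feasible is None:
        raise StateMachineError(
            "MITIGATE with concentration still above the reference level "
            "requires mitigation_feasible"
        )
    return WorkflowState.MITIGATE if mitigation_feasible else WorkflowState.OPERATIONAL_MITIGATION


@dataclass(frozen=True)
class ComplianceReport:
    """Per-worker annual doses with categories, plus workforce totals."""

    year: int
    per_worker: pd.DataFrame  # worker_id, name, status, dose_msv, category, compliant
    summary: dict

    def to_csv(self) -> str:
        return self.per_worker.to_csv(index=False)

    def to_json(self) -> str:
        import json

        frame = self.per_worker.to_dict(orient="records")
        return json.dumps({"year": self.year, "workers": frame, "summary": self.summary})


def annual_compliance_report(
    workers: WorkerRegistry, ledger: Ledger, year: int, params: DoseParameters
) -> ComplianceReport:
    """One row per registered worker: accumulated dose, category, compliance.

    The report classifies whatever the ledger contains — including
    over-limit doses imported from outside the planner; the planner
    prevents, the report detects.  The summary gives workforce max and mean
    dose and the count per category (counts partition the workforce).
    """
    rows = []
    for worker in sorted(workers, key=lambda w: w.worker_id):
        dose = ledger.accumulated_dose(worker.worker_id, year)
        assessment = dose_model.classify_annual_dose(dose, worker.status, params)
        rows.append(
            {
                "worker_id": worker.worker_id,
                "name": worker.name,
                "status": worker.status,
                "dose_msv": dose,
                "category": assessment.category.value,
                "compliant": assessment.compliant,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["worker_id", "name", "status", "dose_msv", "category", "compliant"],
    )
    doses = frame["dose_msv"] if rows else pd.Series(dtype=float)
    summary = {
        "n_workers": len(rows),
        "max_dose_msv": float(doses.max()) if rows else 0.0,
        "mean_dose_msv": float(doses.mean()) if rows else 0.0,
        "count_by_category": {
            cat.value: int((frame["category"] == cat.value).sum()) if rows else 0
            for cat in WorkerCategory
        },
        "n_noncompliant": int((~frame["compliant"]).sum()) if rows else 0,
    }
    return ComplianceReport(year=year, per_worker=frame, summary=summary)
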