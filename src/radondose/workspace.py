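"""Workspace: registries + planner + workflow states behind one audit log.

Every state-changing operation appends one audit record (who/when/what),
and replaying the audit log from scratch reconstructs the final domain
state exactly.  The wall clock is injectable so replays and tests are
deterministic; replay feeds each record's stored timestamp back in.
"""

from __future__ import annotations

from datetime import date, datetime, timezone
from pathlib import Path
from typing import Callable

from . import compliance, io, registry
from .compliance import WorkflowState, initial_workflow_state, next_workflow_state
from .dose_model import DoseParameters
from .errors import NotFoundError
from .planner import Job, Planner
from .registry import (
    DoseEntry,
    Ledger,
    SiteRegistry,
    Worker,
    WorkerRegistry,
    Worksite,
    measurement_validity,
)


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class Workspace:
    """All mutable tool state for one employer, with an audit trail."""

    def __init__(
        self,
        params: DoseParameters | None = None,
        actor: str = "operator",
        clock: Callable[[], str] = _utc_now,
    ):
        self.params = params or DoseParameters()
        self.actor = actor
        self.clock = clock
        self.sites = SiteRegistry()
        self.workers = WorkerRegistry()
        self.planner = Planner(self.sites, self.workers, self.params)
        self.workflow_states: dict[str, WorkflowState] = {}
        self.audit: list[dict] = []

    # -- audit --------------------------------------------------------------

    def _record(self, action: str, data: dict, timestamp: str | None = None) -> None:
        self.audit.append(
            {
                "seq": len(self.audit),
                "at": timestamp if timestamp is not None else self.clock(),
                "actor": self.actor,
                "action": action,
                "data": data,
            }
        )

    # -- registration -------------------------------------------------------

    def add_site(self, site: Worksite, timestamp: str | None = None):
        stored, validity = self.sites.register(site, self.params)
        self._record(
            "add_site",
            {"site": _site_record(site), "validity": validity.value},
            timestamp,
        )
        return stored, validity

    def add_worker(self, worker: Worker, timestamp: str | None = None) -> Worker:
        stored = self.workers.register(worker)
        self._record(
            "add_worker",
            {"worker": {"worker_id": worker.worker_id, "name": worker.name, "status": worker.status}},
            timestamp,
        )
        return stored

    def import_dose_entry(self, entry: DoseEntry, timestamp: str | None = None) -> None:
        """Import a historical dose credit from outside the planner.

        The planner prevents over-limit assignments; imported history may
        legitimately contain over-limit doses, which reports must detect.
        """
        self.workers.get(entry.worker_id)
        self.planner.ledger.append(entry)
        self._record("import_dose_entry", io.entry_to_record(entry), timestamp)

    # -- planning -----------------------------------------------------------

    def plan_job(self, job: Job, timestamp: str | None = None) -> Job:
        planned = self.planner.plan_job(job)
        self._record("plan_job", io.job_to_record(planned), timestamp)
        return planned

    def confirm_job(self, job_id: str, timestamp: str | None = None) -> Job:
        ts = timestamp if timestamp is not None else self.clock()
        confirmed = self.planner.confirm_job(job_id, timestamp=ts)
        self._record("confirm_job", {"job_id": job_id}, ts)
        return confirmed

    def edit_job(self, job_id: str, timestamp: str | None = None, **changes) -> Job:
        ts = timestamp if timestamp is not None else self.clock()
        edited = self.planner.edit_job(job_id, timestamp=ts, **changes)
        data = {"job_id": job_id}
        data.update(
            {
                k: (v.isoformat() if isinstance(v, date) else list(v) if isinstance(v, tuple) else v)
                for k, v in changes.items()
            }
        )
        self._record("edit_job", data, ts)
        return edited

    def delete_job(self, job_id: str, timestamp: str | None = None) -> Job:
        deleted = self.planner.delete_job(job_id)
        self._record("delete_job", {"job_id": job_id}, timestamp)
        return deleted

    # -- regulatory workflow -------------------------------------------------

    def workflow_state(self, site_id: str) -> WorkflowState:
        if site_id not in self.workflow_states:
            site = self.sites.get(site_id)
            self.workflow_states[site_id] = initial_workflow_state(site, self.params)
        return self.workflow_states[site_id]

    def advance_workflow(
        self,
        site_id: str,
        measured_concentration: float | None = None,
        mitigation_feasible: bool | None = None,
        timestamp: str | None = None,
    ) -> WorkflowState:
        current = self.workflow_state(site_id)
        new = next_workflow_state(
            current, measured_concentration, mitigation_feasible, self.params
        )
        self.workflow_states[site_id] = new
        self._record(
            "advance_workflow",
            {
                "site_id": site_id,
                "from": current.value,
                "to": new.value,
                "measured_concentration": measured_concentration,
                "mitigation_feasible": mitigation_feasible,
            },
            timestamp,
        )
        return new

    # -- views ---------------------------------------------------------------

    def accumulated_dose(self, worker_id: str, year: int) -> float:
        return registry.accumulated_dose(worker_id, year, self.planner.ledger, self.workers)

    def annual_report(self, year: int) -> compliance.ComplianceReport:
        return compliance.annual_compliance_report(
            self.workers, self.planner.ledger, year, self.params
        )

    # -- state snapshot / replay ---------------------------------------------

    def snapshot(self) -> dict:
        """Canonical domain state, for equality checks and audit replay."""
        return {
            "sites": [_site_record(s) for s in sorted(self.sites, key=lambda s: s.site_id)],
            "workers": [
                {"worker_id": w.worker_id, "name": w.name, "status": w.status}
                for w in sorted(self.workers, key=lambda w: w.worker_id)
            ],
            "jobs": sorted(
                (io.job_to_record(j) for j in self.planner.jobs.values()),
                key=lambda r: r["job_id"],
            ),
            "ledger": [io.entry_to_record(e) for e in registry.sorted_entries(self.planner.ledger)],
            "workflow_states": {k: v.value for k, v in sorted(self.workflow_states.items())},
        }

    @classmethod
    def replay(
        cls, audit_records: list[dict], params: DoseParameters | None = None
    ) -> "Workspace":
        """Rebuild a workspace by re-applying an audit log from scratch."""
        ws = cls(params=params)
        for rec in audit_records:
            action, data, ts = rec["action"], rec["data"], rec.get("at")
            if action == "add_site":
                ws.add_site(_site_from_record(data["site"]), timestamp=ts)
            elif action == "add_worker":
                w = data["worker"]
                ws.add_worker(Worker(w["worker_id"], w["name"], w["status"]), timestamp=ts)
            elif action == "import_dose_entry":
                ws.import_dose_entry(
                    DoseEntry(
                        entry_id=data["entry_id"],
                        worker_id=data["worker_id"],
                        job_id=data["job_id"],
                        dose=float(data["dose"]),
                        attribution_year=int(data["attribution_year"]),
                        job_date=date.fromisoformat(data["job_date"]),
                    ),
                    timestamp=ts,
                )
            elif action == "plan_job":
                ws.plan_job(io.job_from_record(data), timestamp=ts)
            elif action == "confirm_job":
                ws.confirm_job(data["job_id"], timestamp=ts)
            elif action == "edit_job":
                changes = {k: v for k, v in data.items() if k != "job_id"}
                if "start_date" in changes and changes["start_date"] is not None:
                    changes["start_date"] = date.fromisoformat(changes["start_date"])
                for key in ("add_workers", "remove_workers"):
                    if key in changes:
                        changes[key] = tuple(changes[key])
                ws.edit_job(data["job_id"], timestamp=ts, **changes)
            elif action == "delete_job":
                ws.delete_job(data["job_id"], timestamp=ts)
            elif action == "advance_workflow":
                ws.advance_workflow(
                    data["site_id"],
                    data.get("measured_concentration"),
                    data.get("mitigation_feasible"),
                    timestamp=ts,
                )
            else:
                raise NotFoundError(f"unknown audit action {action!r}")
        return ws

    # -- persistence ----------------------------------------------------------

    def save(self, data_dir: str | Path) -> None:
        data_dir = Path(data_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
        io.write_text(data_dir / "sites.csv", io.sites_to_csv(list(self.sites)))
        io.write_text(data_dir / "workers.csv", io.workers_to_csv(list(self.workers)))
        io.write_text(
            data_dir / "jobs.jsonl", io.jobs_to_jsonl(list(self.planner.jobs.values()))
        )
        io.write_text(data_dir / "ledger.jsonl", io.ledger_to_jsonl(self.planner.ledger))
        io.write_text(data_dir / "audit.jsonl", io.audit_to_jsonl(self.audit))
        import json

        io.write_text(
            data_dir / "workflow.json",
            json.dumps({k: v.value for k, v in self.workflow_states.items()}, indent=2),
        )

    @classmethod
    def load(cls, data_dir: str | Path, params: DoseParameters | None = None) -> "Workspace":
        data_dir = Path(data_dir)
        ws = cls(params=params)
        for site in io.sites_from_csv(io.read_text(data_dir / "sites.csv")):
            ws.sites.register(site, ws.params)
        for worker in io.workers_from_csv(io.read_text(data_dir / "workers.csv")):
            ws.workers.register(worker)
        for job in io.jobs_from_jsonl(io.read_text(data_dir / "jobs.jsonl")):
            ws.planner.jobs[job.job_id] = job
        ws.planner.ledger = io.ledger_from_jsonl(io.read_text(data_dir / "ledger.jsonl"))
        ws.audit = io.audit_from_jsonl(io.read_text(data_dir / "audit.jsonl"))
        workflow_path = data_dir / "workflow.json"
        if workflow_path.exists():
            import json

            raw = json.loads(io.read_text(workflow_path))
            ws.workflow_states = {k: WorkflowState(v) for k, v in raw.items()}
        return ws


def _site_record(site: Worksite) -> dict:
    return {
        "site_id": site.site_id,
        "name": site.name,
        "annual_mean_concentration": site.annual_mean_concentration,
        "measurement_start": site.measurement_start.isoformat(),
        "measurement_end": site.measurement_end.isoformat(),
        "occupancy_hours_per_year": site.occupancy_hours_per_year,
        "location_flags": {
            f: getattr(site.location_flags, f) for f in registry.LOCATION_FLAG_NAMES
        },
    }


def _site_from_record(rec: dict) -> Worksite:
    return Worksite(
        site_id=rec["site_id"],
        name=rec["name"],
        annual_mean_concentration=float(rec["annual_mean_concentration"]),
        measurement_start=date.fromisoformat(rec["measurement_start"]),
        measurement_end=date.fromisoformat(rec["measurement_end"]),
        occupancy_hours_per_year=float(rec["occupancy_hours_per_year"]),
        location_flags=registry.LocationFlags(**rec["location_flags"]),
    )
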