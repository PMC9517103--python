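"""Constraint-checked job planning against the category-B dose ceiling.

The planner is the tool's safety mechanism: a job can only be assigned to
workers whose accumulated annual dose plus the job's per-person dose
increment stays within their applicable limit — the 6 mSv category-B ceiling
(inclusive) for standard workers, the strict 1 mSv limit for pregnant,
breastfeeding or minor workers.  Any operation that would breach a limit is
rejected atomically: the job list and ledger are left untouched and the
error carries the full comparison (accumulated, increment, limit) for every
offending worker.

Workflow: plan → (dashboard, PLANNED) → confirm (CONFIRMED) or edit
(EDITED, ledger rebuilt from scratch).  Assignment suggestions distribute
dose as evenly as possible by greedily picking the available workers with
the lowest accumulated doses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date

from . import dose_model, registry
from .dose_model import DoseParameters
from .errors import (
    ConflictError,
    DoseLimitError,
    InfeasibleError,
    NotFoundError,
    PlanningBlockedError,
    ValidationError,
)
from .registry import (
    Ledger,
    MeasurementValidity,
    SiteRegistry,
    WorkerRegistry,
    Worksite,
    measurement_validity,
)


class JobState(enum.Enum):
    PLANNED = "PLANNED"
    CONFIRMED = "CONFIRMED"
    EDITED = "EDITED"


@dataclass(frozen=True)
class Job:
    """A planned or completed unit of work at one site."""

    job_id: str
    site_id: str
    start_date: date
    duration: float  # hours
    assigned_worker_ids: tuple[str, ...]
    state: JobState = JobState.PLANNED
    last_edited: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(
                f"duration must be > 0 hours, got {self.duration} (job {self.job_id})"
            )
        ids = tuple(self.assigned_worker_ids)
        object.__setattr__(self, "assigned_worker_ids", ids)
        if not ids:
            raise ValidationError(f"job {self.job_id} has no assigned workers")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"job {self.job_id} assigns a worker more than once")


def job_increment(job: Job, site: Worksite, params: DoseParameters) -> float:
    """Per-person dose increment of a job in mSv.

    Every assigned worker is co-present for the full duration, so the
    increment is the same for all of them and independent of crew size.
    Planning on a site whose measurement is invalid is blocked.
    """
    if measurement_validity(site, params) is not MeasurementValidity.VALID:
        raise PlanningBlockedError(
            f"site {site.site_id!r} has an invalid radon measurement "
            f"({site.measurement_days} days < {params.min_measurement_days:.0f}); "
            "remeasure before planning"
        )
    return dose_model.effective_dose(site.annual_mean_concentration, job.duration, params)


class Planner:
    """Dashboard of jobs plus the dose ledger they imply.

    Holds references to the site and worker registries; every mutation is
    validated first so a rejected operation leaves all state unchanged.
    """

    def __init__(
        self,
        sites: SiteRegistry,
        workers: WorkerRegistry,
        params: DoseParameters,
        ledger: Ledger | None = None,
    ):
        self.sites = sites
        self.workers = workers
        self.params = params
        self.ledger = ledger if ledger is not None else Ledger()
        self.jobs: dict[str, Job] = {}

    # -- dose accounting ----------------------------------------------------

    def accumulated_for_planning(self, worker_id: str, as_of: date) -> float:
        """Accumulated dose relevant to a job starting on ``as_of``."""
        if self.params.annual_window == "rolling":
            return self.ledger.accumulated_dose_rolling(worker_id, as_of)
        return self.ledger.accumulated_dose(worker_id, as_of.year)

    def increment_for(self, site_id: str, duration: float, start_date: date) -> float:
        site = self.sites.get(site_id)
        probe = Job(
            job_id="__probe__",
            site_id=site_id,
            start_date=start_date,
            duration=duration,
            assigned_worker_ids=("__probe__",),
        )
        return job_increment(probe, site, self.params)

    # -- availability -------------------------------------------------------

    def available_workers(
        self, site_id: str, start_date: date, duration: float
    ) -> list[registry.Worker]:
        """Exactly the workers who could take this job without breaching limits.

        A worker is available iff accumulated dose + increment is within
        their status's ceiling (inclusive 6 mSv for standard, strict 1 mSv
        for special statuses).  An empty result is a legal outcome.
        """
        increment = self.increment_for(site_id, duration, start_date)
        available = []
        for worker in self.workers:
            acc = self.accumulated_for_planning(worker.worker_id, start_date)
            if dose_model.within_limit(acc + increment, worker.status, self.params):
                available.append(worker)
        return sorted(available, key=lambda w: w.worker_id)

    # -- planning -----------------------------------------------------------

    def _check_assignment(self, job: Job) -> None:
        """Raise DoseLimitError listing every over-limit worker, or return."""
        site = self.sites.get(job.site_id)
        increment = job_increment(job, site, self.params)
        violations = []
        for worker_id in job.assigned_worker_ids:
            worker = self.workers.get(worker_id)
            acc = self.accumulated_for_planning(worker_id, job.start_date)
            limit, inclusive = dose_model.availability_limit(worker.status, self.params)
            total = acc + increment
            if not (total <= limit if inclusive else total < limit):
                violations.append(
                    {
                        "worker_id": worker_id,
                        "accumulated": acc,
                        "increment": increment,
                        "total": total,
                        "limit": limit,
                        "limit_inclusive": inclusive,
                    }
                )
        if violations:
            raise DoseLimitError(violations)

    def plan_job(self, job: Job) -> Job:
        """Admit a job to the dashboard and credit provisional doses.

        Succeeds iff every assigned worker is available; otherwise raises
        :class:`DoseLimitError` naming each offending worker and leaves the
        dashboard and ledger byte-identical.
        """
        if job.job_id in self.jobs:
            raise ConflictError(f"job_id {job.job_id!r} already planned")
        self._check_assignment(job)
        site = self.sites.get(job.site_id)
        planned = replace(job, state=JobState.PLANNED)
        for entry in registry.make_entries(planned, site, self.params):
            self.ledger.append(entry)
        self.jobs[planned.job_id] = planned
        return planned

    def confirm_job(self, job_id: str, timestamp: str | None = None) -> Job:
        """Freeze a planned job as carried out; doses are unchanged."""
        job = self._get_job(job_id)
        confirmed = replace(job, state=JobState.CONFIRMED, last_edited=timestamp)
        self.jobs[job_id] = confirmed
        return confirmed

    def edit_job(
        self,
        job_id: str,
        *,
        site_id: str | None = None,
        start_date: date | None = None,
        duration: float | None = None,
        add_workers: tuple[str, ...] = (),
        remove_workers: tuple[str, ...] = (),
        timestamp: str | None = None,
    ) -> Job:
        """Apply changes to a job, then rebuild the ledger from scratch.

        The edited job must itself pass the availability check against the
        post-edit ledger (the job's own previous entries excluded); a
        limit-violating edit is refused with the same error contract as
        :meth:`plan_job` and leaves everything unchanged.
        """
        job = self._get_job(job_id)
        workers = [w for w in job.assigned_worker_ids if w not in set(remove_workers)]
        for w in add_workers:
            if w in workers:
                raise ConflictError(f"worker {w!r} already assigned to job {job_id!r}")
            workers.append(w)
        edited = replace(
            job,
            site_id=site_id if site_id is not None else job.site_id,
            start_date=start_date if start_date is not None else job.start_date,
            duration=duration if duration is not None else job.duration,
            assigned_worker_ids=tuple(workers),
            state=JobState.EDITED,
            last_edited=timestamp,
        )
        # Validate against the ledger with this job's old entries removed.
        trial_jobs = [j for j in self.jobs.values() if j.job_id != job_id]
        trial_ledger = registry.recompute_ledger(
            trial_jobs, self.sites, self.workers, self.params
        )
        trial = Planner(self.sites, self.workers, self.params, ledger=trial_ledger)
        trial._check_assignment(edited)

        self.jobs[job_id] = edited
        self.ledger = registry.recompute_ledger(
            self.jobs.values(), self.sites, self.workers, self.params
        )
        return edited

    def delete_job(self, job_id: str) -> Job:
        """Remove a job and exactly its ledger entries."""
        job = self._get_job(job_id)
        del self.jobs[job_id]
        self.ledger.remove_job(job_id)
        return job

    # -- suggestion ---------------------------------------------------------

    def suggest_assignment(
        self, site_id: str, start_date: date, duration: float, n: int
    ) -> list[registry.Worker]:
        """The n available workers with the lowest accumulated doses.

        Greedy min-dose-first with ties broken by worker_id ascending; at a
        one-job horizon this minimises the maximum post-job accumulated dose
        over all size-n subsets of available workers, which is how "dose as
        evenly distributed as possible" is operationalised.  The suggestion
        always passes :meth:`plan_job`.
        """
        if n < 0:
            raise ValidationError(f"n must be >= 0, got {n}")
        if n == 0:
            return []
        available = self.available_workers(site_id, start_date, duration)
        if len(available) < n:
            raise InfeasibleError(
                f"need {n} workers but only {len(available)} are available",
                available=len(available),
                required=n,
            )
        ranked = sorted(
            available,
            key=lambda w: (self.accumulated_for_planning(w.worker_id, start_date), w.worker_id),
        )
        return ranked[:n]

    # -- helpers ------------------------------------------------------------

    def _get_job(self, job_id: str) -> Job:
        try:
            return self.jobs[job_id]
        except KeyError:
            raise NotFoundError(f"unknown job_id {job_id!r}") from None
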