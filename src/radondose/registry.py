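"""Worksite and worker registries and the append-only dose ledger.

Accumulated doses are never stored as running totals: they are always derived
from the ledger, and the ledger itself is a pure function of the job list,
the site registry and the parameters.  That makes every dose figure
re-derivable for audit and lets edits be implemented as a deterministic
rebuild rather than in-place mutation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

from . import dose_model
from .dose_model import DoseParameters
from .errors import ConflictError, IntegrityError, NotFoundError, ValidationError

#: Names of the workplace location criteria that indicate radon potential.
LOCATION_FLAG_NAMES = (
    "radon_prone_area",
    "underground",
    "thermal_or_water_facility",
    "prior_high_levels",
    "nationally_listed",
)


@dataclass(frozen=True)
class LocationFlags:
    """Location criteria from the radon-potential screening checklist."""

    radon_prone_area: bool = False
    underground: bool = False
    thermal_or_water_facility: bool = False
    prior_high_levels: bool = False
    nationally_listed: bool = False

    def true_flags(self) -> list[str]:
        return [name for name in LOCATION_FLAG_NAMES if getattr(self, name)]


class MeasurementValidity(enum.Enum):
    VALID = "VALID"
    INVALID = "INVALID"


@dataclass(frozen=True)
class Worksite:
    """A measured work zone.

    ``annual_mean_concentration`` is the annual mean radon concentration in
    Bq/m³ obtained from a measurement spanning ``measurement_start`` to
    ``measurement_end``; ``occupancy_hours_per_year`` is the estimated total
    occupancy used by the radon-potential screen.
    """

    site_id: str
    name: str
    annual_mean_concentration: float
    measurement_start: date
    measurement_end: date
    occupancy_hours_per_year: float = 0.0
    location_flags: LocationFlags = field(default_factory=LocationFlags)

    def __post_init__(self) -> None:
        if self.annual_mean_concentration < 0:
            raise ValidationError(
                f"annual_mean_concentration must be >= 0 Bq/m³, got "
                f"{self.annual_mean_concentration} (site {self.site_id})"
            )
        if self.measurement_end < self.measurement_start:
            raise ValidationError(
                f"measurement_end precedes measurement_start for site {self.site_id}"
            )
        if self.occupancy_hours_per_year < 0:
            raise ValidationError(
                f"occupancy_hours_per_year must be >= 0, got "
                f"{self.occupancy_hours_per_year} (site {self.site_id})"
            )

    @property
    def measurement_days(self) -> int:
        return (self.measurement_end - self.measurement_start).days


def measurement_validity(site: Worksite, params: DoseParameters) -> MeasurementValidity:
    """VALID iff the radon measurement spans at least the minimum duration.

    The minimum is ``params.min_measurement_months`` counted at 30 days per
    month (60 days for the default two-month rule).
    """
    if site.measurement_days >= params.min_measurement_days:
        return MeasurementValidity.VALID
    return MeasurementValidity.INVALID


@dataclass(frozen=True)
class Worker:
    """An identified person with a protection status."""

    worker_id: str
    name: str
    status: str = "standard"

    def __post_init__(self) -> None:
        if self.status not in dose_model.WORKER_STATUSES:
            raise ValidationError(
                f"unknown worker status {self.status!r} for worker {self.worker_id}"
            )


@dataclass(frozen=True)
class DoseEntry:
    """One worker-job dose credit in mSv, attributed to a calendar year."""

    entry_id: str
    worker_id: str
    job_id: str
    dose: float
    attribution_year: int
    job_date: date

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0 mSv, got {self.dose}")


class SiteRegistry:
    """Registered worksites keyed by unique site_id, with validity verdicts."""

    def __init__(self) -> None:
        self._sites: dict[str, Worksite] = {}

    def register(
        self, site: Worksite, params: DoseParameters
    ) -> tuple[Worksite, MeasurementValidity]:
        if site.site_id in self._sites:
            raise ConflictError(f"site_id {site.site_id!r} already registered")
        self._sites[site.site_id] = site
        return site, measurement_validity(site, params)

    def update(self, site: Worksite) -> None:
        """Replace an existing site record (remeasurement)."""
        if site.site_id not in self._sites:
            raise NotFoundError(f"unknown site_id {site.site_id!r}")
        self._sites[site.site_id] = site

    def get(self, site_id: str) -> Worksite:
        try:
            return self._sites[site_id]
        except KeyError:
            raise NotFoundError(f"unknown site_id {site_id!r}") from None

    def __contains__(self, site_id: str) -> bool:
        return site_id in self._sites

    def __iter__(self):
        return iter(self._sites.values())

    def __len__(self) -> int:
        return len(self._sites)


class WorkerRegistry:
    """Registered workers keyed by unique worker_id."""

    def __init__(self) -> None:
        self._workers: dict[str, Worker] = {}

    def register(self, worker: Worker) -> Worker:
        if worker.worker_id in self._workers:
            raise ConflictError(f"worker_id {worker.worker_id!r} already registered")
        self._workers[worker.worker_id] = worker
        return worker

    def get(self, worker_id: str) -> Worker:
        try:
            return self._workers[worker_id]
        except KeyError:
            raise NotFoundError(f"unknown worker_id {worker_id!r}") from None

    def __contains__(self, worker_id: str) -> bool:
        return worker_id in self._workers

    def __iter__(self):
        return iter(self._workers.values())

    def __len__(self) -> int:
        return len(self._workers)


class Ledger:
    """Append-only collection of dose entries, one per (worker, job) pair."""

    def __init__(self, entries: list[DoseEntry] | None = None):
        self._entries: list[DoseEntry] = []
        self._keys: set[tuple[str, str]] = set()
        # per-(worker, year) entry index so availability checks stay O(own
        # entries) rather than O(whole ledger) under long job streams
        self._by_worker_year: dict[tuple[str, int], list[DoseEntry]] = {}
        for entry in entries or []:
            self.append(entry)

    def append(self, entry: DoseEntry) -> None:
        key = (entry.worker_id, entry.job_id)
        if key in self._keys:
            raise ConflictError(
                f"worker {entry.worker_id!r} already credited for job {entry.job_id!r}"
            )
        self._keys.add(key)
        self._entries.append(entry)
        self._by_worker_year.setdefault(
            (entry.worker_id, entry.attribution_year), []
        ).append(entry)

    def remove_job(self, job_id: str) -> list[DoseEntry]:
        """Drop all entries of one job (used when an edit rebuilds them)."""
        removed = [e for e in self._entries if e.job_id == job_id]
        self._entries = [e for e in self._entries if e.job_id != job_id]
        self._keys -= {(e.worker_id, e.job_id) for e in removed}
        for e in removed:
            bucket = self._by_worker_year[(e.worker_id, e.attribution_year)]
            bucket.remove(e)
        return removed

    def accumulated_dose(self, worker_id: str, year: int) -> float:
        """Exact sum of this worker's entries attributed to ``year``."""
        return sum(
            e.dose for e in self._by_worker_year.get((worker_id, year), ())
        )

    def accumulated_dose_rolling(self, worker_id: str, as_of: date) -> float:
        """Sum over the 365-day window ending at ``as_of`` (inclusive)."""
        window_start = as_of - timedelta(days=364)
        return sum(
            e.dose
            for e in self._entries
            if e.worker_id == worker_id and window_start <= e.job_date <= as_of
        )

    def entries(self) -> list[DoseEntry]:
        return list(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ledger):
            return NotImplemented
        return sorted_entries(self) == sorted_entries(other)

    def copy(self) -> "Ledger":
        return Ledger(self._entries)


def sorted_entries(ledger: Ledger) -> list[DoseEntry]:
    """Entries in the canonical (date, job, worker) order used for rebuilds."""
    return sorted(ledger.entries(), key=lambda e: (e.job_date, e.job_id, e.worker_id))


def accumulated_dose(worker_id: str, year: int, ledger: Ledger, workers: WorkerRegistry) -> float:
    """Accumulated dose of a registered worker for one calendar year, in mSv.

    A registered worker with no entries returns 0; an unknown worker raises
    :class:`~radondose.errors.NotFoundError`.
    """
    workers.get(worker_id)  # raises NotFoundError if unregistered
    return ledger.accumulated_dose(worker_id, year)


def make_entries(job, site: Worksite, params: DoseParameters) -> list[DoseEntry]:
    """Dose entries for one job: the same per-person dose for every worker."""
    dose = dose_model.effective_dose(
        site.annual_mean_concentration, job.duration, params
    )
    return [
        DoseEntry(
            entry_id=f"{job.job_id}:{worker_id}",
            worker_id=worker_id,
            job_id=job.job_id,
            dose=dose,
            attribution_year=job.start_date.year,
            job_date=job.start_date,
        )
        for worker_id in sorted(job.assigned_worker_ids)
    ]


def recompute_ledger(
    jobs, sites: SiteRegistry, workers: WorkerRegistry, params: DoseParameters
) -> Ledger:
    """Rebuild the entire ledger from the job list alone, deterministically.

    The output depends only on (jobs, sites, params) — never on the order in
    which jobs were created or edited.  Dangling site or worker references
    raise :class:`~radondose.errors.IntegrityError` listing every one.
    """
    dangling: list[str] = []
    for job in jobs:
        if job.site_id not in sites:
            dangling.append(f"job {job.job_id}: site {job.site_id}")
        for wid in job.assigned_worker_ids:
            if wid not in workers:
                dangling.append(f"job {job.job_id}: worker {wid}")
    if dangling:
        raise IntegrityError(
            "dangling references: " + "; ".join(dangling), dangling=dangling
        )
    ledger = Ledger()
    for job in sorted(jobs, key=lambda j: (j.start_date, j.job_id)):
        for entry in make_entries(job, sites.get(job.site_id), params):
            ledger.append(entry)
    return ledger
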