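from __future__ import annotations

from datetime import date, timedelta

import pytest

from radondose import (
    DoseParameters,
    Job,
    Planner,
    SiteRegistry,
    Worker,
    WorkerRegistry,
    Worksite,
)
from radondose.registry import LocationFlags


@pytest.fixture
def params() -> DoseParameters:
    return DoseParameters()


def make_site(
    site_id: str = "S1",
    concentration: float = 400.0,
    span_days: int = 90,
    occupancy: float = 1600.0,
    **flags,
) -> Worksite:
    start = date(2024, 10, 1)
    return Worksite(
        site_id=site_id,
        name=f"site {site_id}",
        annual_mean_concentration=concentration,
        measurement_start=start,
        measurement_end=start + timedelta(days=span_days),
        occupancy_hours_per_year=occupancy,
        location_flags=LocationFlags(**flags),
    )


def make_planner(
    sites: list[Worksite],
    workers: list[Worker],
    params: DoseParameters | None = None,
) -> Planner:
    params = params or DoseParameters()
    site_reg = SiteRegistry()
    for s in sites:
        site_reg.register(s, params)
    worker_reg = WorkerRegistry()
    for w in workers:
        worker_reg.register(w)
    return Planner(site_reg, worker_reg, params)


def make_job(
    job_id: str = "J1",
    site_id: str = "S1",
    hours: float = 8.0,
    workers: tuple[str, ...] = ("W1",),
    start: date = date(2025, 3, 1),
) -> Job:
    return Job(
        job_id=job_id,
        site_id=site_id,
        start_date=start,
        duration=hours,
        assigned_worker_ids=workers,
    )


@pytest.fixture
def crew() -> list[Worker]:
    return [
        Worker("W1", "Ana"),
        Worker("W2", "Breogan"),
        Worker("W3", "Carme"),
    ]
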