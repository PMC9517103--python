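"""Compliant job planning: availability, the error box, and suggestions.

Reproduces the planner's core behaviour: a worker who has accumulated
5.6 mSv cannot take a job that would add 0.5 mSv (5.6 + 0.5 > 6 mSv), the
rejection reports the full comparison, and the suggestion engine picks the
lowest-dose crew so exposure stays evenly distributed.
"""

from datetime import date, timedelta

from radondose import (
    DoseEntry,
    DoseLimitError,
    DoseParameters,
    Job,
    Planner,
    SiteRegistry,
    Worker,
    WorkerRegistry,
    Worksite,
)
from radondose.registry import LocationFlags

params = DoseParameters()
sites, workers = SiteRegistry(), WorkerRegistry()
sites.register(
    Worksite(
        site_id="CELLAR",
        name="cellar workshop",
        annual_mean_concentration=400.0,  # above the 300 Bq/m³ reference level
        measurement_start=date(2024, 10, 1),
        measurement_end=date(2025, 1, 10),  # > two months: VALID
        occupancy_hours_per_year=900.0,
        location_flags=LocationFlags(underground=True),
    ),
    params,
)
for wid, name in [("W1", "Ana"), ("W2", "Breogan"), ("W3", "Carme")]:
    workers.register(Worker(wid, name))

planner = Planner(sites, workers, params)

# Ana already carries 5.6 mSv this year (historical credit).
planner.ledger.append(DoseEntry("H1:W1", "W1", "H1", 5.6, 2025, date(2025, 1, 15)))

# A job whose per-person increment is 0.5 mSv: 400 Bq/m³ × ~186.6 h × 6.7e-6.
hours = 0.5 / (400.0 * params.dose_coefficient)
when = date(2025, 3, 1)
print(f"job increment: {planner.increment_for('CELLAR', hours, when):.3f} mSv/worker")

available = planner.available_workers("CELLAR", when, hours)
print("available workers:", [w.worker_id for w in available])  # no W1

try:
    planner.plan_job(
        Job(job_id="J1", site_id="CELLAR", start_date=when,
            duration=hours, assigned_worker_ids=("W1",))
    )
except DoseLimitError as exc:
    v = exc.violations[0]
    print(
        f"REJECTED: {v['worker_id']} at {v['accumulated']:.1f} mSv + "
        f"{v['increment']:.1f} mSv would exceed the {v['limit']:.0f} mSv ceiling"
    )
print(f"ledger untouched: W1 still at {planner.ledger.accumulated_dose('W1', 2025):.1f} mSv")

# Suggestion: the two lowest-dose available workers take the job instead.
crew = planner.suggest_assignment("CELLAR", when, hours, n=2)
planner.plan_job(
    Job(job_id="J1", site_id="CELLAR", start_date=when, duration=hours,
        assigned_worker_ids=tuple(w.worker_id for w in crew))
)
print("suggested crew planned:", [w.worker_id for w in crew])
for wid in ("W1", "W2", "W3"):
    print(f"  {wid}: {planner.ledger.accumulated_dose(wid, 2025):.2f} mSv in 2025")
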