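"""A synthetic multisite employer: planning season, reports, exports.

Generates a plausible scenario (lognormal radon concentrations, some sites
above the reference level), routes the whole job stream through the
planner, and prints the annual compliance report and a quarterly dashboard
export — the documents an inspector would ask for.
"""

from radondose import DoseLimitError, DoseParameters, Workspace
from radondose.fixtures import ScenarioSpec, generate_scenario
from radondose.reporting import export_history, quarter_range

params = DoseParameters()
scenario = generate_scenario(
    ScenarioSpec(
        n_sites=6, n_workers=8, job_stream_length=400,
        duration_median_hours=80.0,  # a demanding season of long shifts
        rng_seed=2025,
    )
)

ws = Workspace(params=params)
for site in scenario.sites:
    ws.add_site(site)
for worker in scenario.workers:
    ws.add_worker(worker)

planned = rejected = 0
for job in scenario.jobs:
    try:
        ws.plan_job(job)
        planned += 1
    except DoseLimitError:
        rejected += 1  # the planner held the line at the ceiling
print(f"{planned} jobs planned, {rejected} rejected by the dose ceiling\n")

report = ws.annual_report(2025)
print(report.per_worker.to_string(index=False))
s = report.summary
print(
    f"\nworkforce: max {s['max_dose_msv']:.2f} mSv, mean {s['mean_dose_msv']:.2f} mSv, "
    f"categories {s['count_by_category']}"
)
# Every dose is ≤ 6 mSv: the ledger was built solely through the planner.

start, end = quarter_range(2025, 2)
export = export_history(list(ws.planner.jobs.values()), ws.sites, ws.planner.ledger, start, end)
print(f"\nQ2 dashboard ({len(export.dashboard)} jobs):")
print(export.dashboard.head(5).to_string(index=False))
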