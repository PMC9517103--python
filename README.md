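# radondose

Occupational radon dose accounting and compliant job planning for employers
with multisite workers.

Radon is a naturally occurring radioactive gas that accumulates indoors and
is, after smoking, the main contributor to lung cancer in many countries.
EU Directive 2013/59/Euratom sets a workplace reference level of 300 Bq/m³
of radon concentration and an effective dose limit of 20 mSv/year. When
building works cannot bring the concentration below the reference level,
the remaining option is *operational mitigation*: controlling each worker's
occupancy time and location so that their annual effective dose stays at or
below 6 mSv — the ceiling of worker **category B**, which spares both
workers (low exposure) and employers (lighter regulatory duties: no
dosimetry or planned-exposure regime). With multisite workers this becomes
a genuine bookkeeping problem — each person accrues dose at a different
rate at each site — and that bookkeeping must be accurate, conservative and
transparent. `radondose` is a library and CLI for exactly that task, aimed
at health-and-safety technicians and the engineers building tools for them.

## The model

The effective dose from radon gas exposure is

```
E [mSv] = C [Bq/m³] × t [h] × DCF
```

where `C` is the annual mean radon concentration of the worksite, `t` the
occupancy time, and `DCF` a dose-conversion coefficient with the
radon–progeny equilibrium factor folded in (default 6.7×10⁻⁶
mSv/(Bq·h·m⁻³), the ICRP Publication 137 workplace convention; it is a
configuration field, since a regulator may mandate another value).

Annual doses classify workers as category B (≤ 6 mSv), category A
(> 6 mSv, up to the inclusive 20 mSv limit) or over-limit; pregnant,
breastfeeding and minor workers carry a strict < 1 mSv limit. The planner
admits a job only if, for **every** assigned worker,

```
accumulated_dose(worker, year) + C_site × t_job × DCF  ≤  limit(status)
```

and rejects it atomically otherwise — that single check, applied to every
plan and every edit, is what guarantees no planner-managed worker ever ends
a year over their ceiling. Crew suggestions pick the `n` available workers
with the lowest accumulated doses (greedy min-dose-first, ties by worker
id), which at a one-job horizon provably minimises the maximum post-job
dose — keeping exposure as evenly distributed as possible.

All doses derive from an append-only ledger that is a pure function of the
job list, so any edit is re-checked and the whole history can be rebuilt
and audited; every state change appends one audit record, and replaying
the audit log reconstructs the final state exactly.

## Worked example

A cellar workshop measured at 400 Bq/m³ (above the reference level,
measurement spanning more than two months so it is valid for planning).
Ana has already accumulated 5.6 mSv this year; a ~187 h job at this site
adds 0.5 mSv per assigned worker:

```python
# condensed from examples/02_plan_and_reject.py
hours = 0.5 / (400.0 * params.dose_coefficient)          # a 0.5 mSv job
available = planner.available_workers("CELLAR", when, hours)
planner.plan_job(Job(job_id="J1", site_id="CELLAR", start_date=when,
                     duration=hours, assigned_worker_ids=("W1",)))
```

```
job increment: 0.500 mSv/worker
available workers: ['W2', 'W3']
REJECTED: W1 at 5.6 mSv + 0.5 mSv would exceed the 6 mSv ceiling
ledger untouched: W1 still at 5.6 mSv
suggested crew planned: ['W2', 'W3']
  W1: 5.60 mSv in 2025
  W2: 0.50 mSv in 2025
  W3: 0.50 mSv in 2025
```

Ana is excluded from the available list because 5.6 + 0.5 > 6 mSv; the
rejection reports the full comparison and leaves the ledger untouched, and
the suggestion engine routes the job to the two lowest-dose colleagues.
The other scripts in `examples/` walk through dose arithmetic and category
boundaries (`01`), the regulatory decision workflow from radon-potential
screening to operational mitigation (`03`), and a full synthetic planning
season with compliance reports and dashboard exports (`04`).

The same operations are available from a shell:

```bash
radondose --data-dir ./data add-site --site-id CELLAR --name "cellar workshop" \
    --concentration 400 --measured-from 2024-10-01 --measured-to 2024-12-15 \
    --occupancy 900 --flag underground
radondose --data-dir ./data add-worker --worker-id W1 --name Ana
radondose --data-dir ./data plan --job-id J1 --site CELLAR \
    --date 2025-03-01 --hours 187 --workers W1
radondose --data-dir ./data report --year 2025
```

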