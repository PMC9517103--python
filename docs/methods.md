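# Methods

## Dose model

Effective dose from workplace radon is modelled as strictly proportional to
activity concentration and occupancy time:

    E [mSv] = C [Bq/m³] × t [h] × DCF [mSv per Bq·h·m⁻³]

A single dose-conversion coefficient `DCF` carries the radon–progeny
equilibrium assumption; the default, 6.7×10⁻⁶ mSv/(Bq·h·m⁻³), is the ICRP
Publication 137 workplace convention at equilibrium factor 0.4. Different
workplaces (mines, show caves) and future ICRP revisions call for different
coefficients, so `DCF` is a configuration field rather than a constant, and
every downstream number is parameterised on it. Thoron, progeny-specific
dosimetry, working-level-month conversions and seasonal correction factors
are out of scope.

The model assumes the site's annual mean concentration applies uniformly to
every hour worked there, and that all workers assigned to a job are
co-present for its full duration. Both are conservative simplifications of
real occupancy patterns: no diurnal/seasonal variation, no partial-presence
factors.

## Regulatory constants and boundary conventions

| parameter | default | unit | boundary |
|---|---|---|---|
| `reference_level` | 300 | Bq/m³ | exactly at level does **not** trigger mitigation (it is a maximum) |
| `category_b_limit` | 6 | mSv/year | inclusive — "6 mSv or less" is category B |
| `annual_dose_limit` | 20 | mSv/year | inclusive for compliance of standard workers |
| `special_status_limit` | 1 | mSv/year | **strict** (<) for pregnant/breastfeeding/minor |
| `potential_occupancy_threshold` | 50 | h/year | **strict** (>) for radon potential |
| `min_measurement_months` | 2 | months | counted as 30 days/month, so ≥ 60 days is valid |

Each convention is decided once here and applied identically in the
classifier, the planner's availability filter and the workflow engine. All
limit comparisons use full-precision values; rounding (2 decimal places,
round-half-even) happens only in the reporting layer, and every rounded
figure is accompanied by a full-precision audit record.

The two-month measurement-validity rule uses a 60-day floor rather than
calendar-month arithmetic, which is locale-fragile and can make "two
months" as short as 59 days; the day-count floor is the conservative,
auditable reading.

## Annual accounting

Dose is attributed to the calendar year of the job's start date. Calendar
years are the default because every regulatory limit is "per year" and
annual reporting is the audit cadence; a rolling-365-day window is
available as the `annual_window` configuration switch for operators who
prefer it. Jobs spanning a year boundary credit their full dose to the
start year — jobs are shift-scale, so pro-rata splitting would add
complexity without changing any compliance outcome materially. This is a
documented limitation for multi-week jobs ending in January.

The ledger is append-only and derived: one entry per (worker, job), and the
entire ledger is a pure function of (jobs, sites, parameters). Edits do not
mutate entries in place; they trigger a deterministic full rebuild (jobs
ordered by start date then job id), so the rebuilt ledger is byte-identical
regardless of edit order, and an incremental ledger can always be verified
against a from-scratch rebuild. Rejected operations are atomic: validation
happens strictly before any mutation.

## Planner

A job is admissible iff every assigned worker's accumulated dose plus the
job's per-person increment stays within their status's ceiling (≤ 6 mSv
standard, < 1 mSv special). Crew suggestion sorts available workers by
(accumulated dose, worker id) and takes the first `n`. "Dose as evenly
distributed as possible" is thus operationalised as greedy
min-dose-first: at a one-job horizon the greedy pick minimises the maximum
post-job accumulated dose over all size-`n` subsets (the increment is
identical for everyone, so minimising the max pre-job dose is equivalent;
verified in tests by exhaustive subset enumeration). Multi-period schedule
optimisation is deliberately out of scope — the workflow is one job at a
time, and a transparent rule is easier to audit than an optimiser.

The planner hard-stops at the category-B ceiling for standard workers; it
does not offer an opt-in category-A (≤ 20 mSv) planning regime, since the
tool's purpose is precisely to keep the workforce out of the
planned-exposure regime. The compliance report, by contrast, classifies
whatever the ledger contains — imported historical doses may exceed any
limit, and the report flags them (the planner prevents, the report
detects).

## Regulatory workflow

The per-site decision chain is a five-state machine: NO_POTENTIAL, MEASURE,
PERIODIC_REMEASURE, MITIGATE, OPERATIONAL_MITIGATION. Radon potential
requires both occupancy strictly over the threshold and at least one
location criterion (radon-prone area, underground, thermal or
underground-water facility, previously detected high levels, nationally
listed). Whether further constructive mitigation is "reasonable" is a human
judgment supplied as an explicit boolean, never inferred. Remeasurement
periodicity is set by national regulators, so the tool stores workflow
state rather than inventing a period. Illegal (state, input) pairs raise
rather than guess; a fuzz test confirms only the declared edges are
reachable.

## Synthetic scenarios

The fixture generator emulates a multisite employer: site concentrations
are lognormal (median 80 Bq/m³, geometric standard deviation 2.5 — the
canonical shape and plausible magnitude for indoor radon), with a target
fraction of sites above the reference level (default 0.27, a realistic
occupational share) realised by a per-site Bernoulli draw followed by
inverse-CDF sampling from the lognormal conditioned on the chosen side of
the level. Job durations are lognormal (median 8 h, GSD 2 — shift-scale
work), crews of 1–3, dates uniform over the year; a configurable fraction
of workers (default 0.1) carry special protection statuses. All
measurements span 70–130 days so generated sites are always valid for
planning. Generation is split into two independent seeded sub-streams
(world vs job stream) so alternative job streams can be drawn for the same
world.

The adversarial stream re-pairs the same drawn durations and site choices
so the longest jobs land at the hottest sites and — given a dose lookup —
targets the currently most-exposed workers, maximising pressure on the
ceiling while preserving the plain stream's marginal distributions. What
passing the never-exceed test shows is that the *planner* holds the line
under hostile load; it does not show that real workloads resemble the
synthetic ones (no spatial or temporal concentration structure, no
correlated demand, no measurement error on the annual means).

## Numerical choices

- Dose arithmetic is plain float64 with no intermediate rounding;
  availability checks compare unrounded values against limits.
- The conservation check (incremental ledger vs from-scratch rebuild)
  tolerates 1e-12 relative error because float addition order differs
  between the two paths; in practice the observed discrepancy is ≈1e-16 mSv.
- Ledger doses are serialised to JSON via full-precision `repr`, so
  reloads are bit-exact.
- Ties in crew suggestion break by ascending worker id — deterministic and
  auditable.
- Degenerate inputs (zero-duration jobs, empty crews, inverted measurement
  periods, negative concentrations) are rejected at construction, not
  silently clamped.

## Problem sizes in tests and the acceptance script

The adversarial never-exceed check runs 10,000 jobs over 12 workers and
8 sites; conservation uses 100 random scenarios of 20 jobs each; greedy
optimality is verified exhaustively on 60 instances of up to 12 workers
(the largest size where subset enumeration is cheap). These sizes give the
properties room to fail while the whole suite runs in seconds.

## Known limitations

- No co-exposure accounting (residential radon, medical imaging, silica).
- No dosimeter-based validation of the concentration × time model; the
  ledger is as good as the site measurements and time tracking fed to it.
- Single-employer, single-operator model: no federation, authentication or
  concurrent-edit semantics.
- Year-boundary jobs credit the start year in full (see above).
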