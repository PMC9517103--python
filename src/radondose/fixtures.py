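"""Synthetic scenarios: worksites, workforces, and randomized job streams.

Indoor radon concentrations are modelled as lognormal (the canonical shape
for indoor radon), parameterised by median and geometric standard deviation.
A target fraction of sites above the 300 Bq/m³ reference level is realised
exactly in expectation by drawing a Bernoulli indicator per site and then
sampling the concentration from the lognormal conditioned on the chosen side
of the reference level (inverse-CDF truncation, no rejection loops).

The adversarial job stream exists to stress the planner's never-exceed
guarantee: it carries the same marginal distributions of durations, sites,
dates and crew sizes as the plain stream from the same seed, but pairs the
longest jobs with the hottest sites and (when given a dose lookup) targets
the most-exposed workers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Iterator

import numpy as np
from scipy import stats

from .dose_model import DoseParameters, WORKER_STATUSES
from .errors import ValidationError
from .planner import Job
from .registry import LocationFlags, Worker, Worksite

_FIRST_NAMES = (
    "Ana", "Breogan", "Carme", "Diego", "Estela", "Fiz", "Gloria", "Hugo",
    "Iria", "Xoan", "Lua", "Martin", "Noa", "Oscar", "Paula", "Roi",
)
_SITE_KINDS = (
    "basement archive", "spa pump room", "water treatment gallery", "show cave",
    "underground car park", "cellar workshop", "tunnel section", "storage vault",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic scenario; same seed → identical scenario.

    ``concentration_median`` (Bq/m³) and ``concentration_gsd`` shape the
    lognormal site-concentration distribution (defaults 80 Bq/m³, GSD 2.5);
    ``fraction_above_reference`` is the target share of sites above the
    reference level (default 0.27, a plausible occupational share).
    Job durations are lognormal with ``duration_median_hours`` and
    ``duration_gsd`` (defaults 8 h, GSD 2 — shift-scale jobs).
    """

    n_sites: int = 8
    n_workers: int = 12
    concentration_median: float = 80.0
    concentration_gsd: float = 2.5
    fraction_above_reference: float = 0.27
    job_stream_length: int = 50
    duration_median_hours: float = 8.0
    duration_gsd: float = 2.0
    max_crew_size: int = 3
    special_status_fraction: float = 0.1
    year: int = 2025
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValidationError(f"n_sites must be positive, got {self.n_sites}")
        if self.n_workers < 0 or self.job_stream_length < 0:
            raise ValidationError("n_workers and job_stream_length must be >= 0")
        if self.n_workers == 0 and self.job_stream_length > 0:
            raise ValidationError(
                "degenerate spec: a nonempty job stream needs at least one worker"
            )
        if not 0.0 <= self.fraction_above_reference <= 1.0:
            raise ValidationError(
                f"fraction_above_reference must be in [0, 1], got "
                f"{self.fraction_above_reference}"
            )
        for name in (
            "concentration_median",
            "concentration_gsd",
            "duration_median_hours",
            "duration_gsd",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.special_status_fraction <= 1.0:
            raise ValidationError("special_status_fraction must be in [0, 1]")


@dataclass
class Scenario:
    """A generated study world: sites, workforce, and a stream of jobs."""

    spec: ScenarioSpec
    sites: list[Worksite] = field(default_factory=list)
    workers: list[Worker] = field(default_factory=list)
    jobs: list[Job] = field(default_factory=list)


def _truncated_lognormal(
    rng: np.random.Generator, median: float, gsd: float, above: bool, bound: float
) -> float:
    """Sample lognormal(median, gsd) conditioned on > bound (or <= bound)."""
    mu, sigma = np.log(median), np.log(gsd)
    z_bound = (np.log(bound) - mu) / sigma
    p = stats.norm.cdf(z_bound)
    u = rng.uniform()
    q = p + u * (1.0 - p) if above else u * p
    # guard the open ends of the quantile function
    q = min(max(q, 1e-12), 1.0 - 1e-12)
    return float(np.exp(mu + sigma * stats.norm.ppf(q)))


def generate_scenario(spec: ScenarioSpec, params: DoseParameters | None = None) -> Scenario:
    """Generate a deterministic scenario from the spec's seed.

    All sites carry measurements spanning well over two months, so every
    generated site is VALID for planning.  The realised number of sites
    above the reference level is binomial around
    ``n_sites * fraction_above_reference``.
    """
    params = params or DoseParameters()
    # Independent sub-streams: the world (sites, workforce) and the job
    # stream, so alternative job streams can be drawn for the same world.
    rng = np.random.default_rng([spec.rng_seed, 0])

    sites: list[Worksite] = []
    meas_start = date(spec.year - 1, 9, 1)
    for i in range(spec.n_sites):
        above = bool(rng.uniform() < spec.fraction_above_reference)
        conc = _truncated_lognormal(
            rng, spec.concentration_median, spec.concentration_gsd,
            above=above, bound=params.reference_level,
        )
        span_days = int(rng.integers(70, 130))  # always >= two months
        prior_draw = bool(rng.uniform() < 0.6)
        flags = LocationFlags(
            radon_prone_area=bool(rng.uniform() < 0.4),
            underground=bool(rng.uniform() < 0.5),
            thermal_or_water_facility=bool(rng.uniform() < 0.15),
            prior_high_levels=above and prior_draw,
            nationally_listed=bool(rng.uniform() < 0.1),
        )
        sites.append(
            Worksite(
                site_id=f"S{i:03d}",
                name=f"{_SITE_KINDS[i % len(_SITE_KINDS)]} {i}",
                annual_mean_concentration=round(conc, 1),
                measurement_start=meas_start,
                measurement_end=meas_start + timedelta(days=span_days),
                occupancy_hours_per_year=float(np.round(rng.uniform(20, 2000), 0)),
                location_flags=flags,
            )
        )

    special = [s for s in WORKER_STATUSES if s != "standard"]
    workers: list[Worker] = []
    for i in range(spec.n_workers):
        is_special = rng.uniform() < spec.special_status_fraction
        status_idx = int(rng.integers(len(special)))
        status = special[status_idx] if is_special else "standard"
        workers.append(
            Worker(
                worker_id=f"W{i:03d}",
                name=f"{_FIRST_NAMES[i % len(_FIRST_NAMES)]} {i}",
                status=status,
            )
        )

    stream_rng = np.random.default_rng([spec.rng_seed, 1])
    jobs = list(
        _job_stream(spec, sites, workers, stream_rng, adversarial=False, dose_lookup=None)
    )
    return Scenario(spec=spec, sites=sites, workers=workers, jobs=jobs)


def _draws(spec: ScenarioSpec, n_sites: int, rng: np.random.Generator):
    """The raw random draws shared by plain and adversarial streams."""
    n = spec.job_stream_length
    mu, sigma = np.log(spec.duration_median_hours), np.log(spec.duration_gsd)
    durations = np.exp(rng.normal(mu, sigma, size=n))
    site_picks = rng.integers(0, n_sites, size=n)
    day_offsets = rng.integers(0, 365, size=n)
    crew_sizes = rng.integers(1, spec.max_crew_size + 1, size=n)
    worker_u = rng.random(size=(n, spec.max_crew_size))
    return durations, site_picks, day_offsets, crew_sizes, worker_u


def _job_stream(
    spec: ScenarioSpec,
    sites: list[Worksite],
    workers: list[Worker],
    rng: np.random.Generator,
    adversarial: bool,
    dose_lookup: Callable[[str, date], float] | None,
) -> Iterator[Job]:
    durations, site_picks, day_offsets, crew_sizes, worker_u = _draws(
        spec, len(sites), rng
    )
    if adversarial:
        # Same marginals, hostile pairing: longest jobs at the hottest of the
        # drawn sites. Sort the drawn site choices by concentration and the
        # durations descending, then re-pair them.
        order = np.argsort(-durations, kind="stable")
        hot_first = sorted(
            range(len(durations)),
            key=lambda i: -sites[site_picks[i]].annual_mean_concentration,
        )
        paired_sites = np.empty_like(site_picks)
        paired_sites[order] = site_picks[hot_first]
        site_picks = paired_sites

    worker_ids = [w.worker_id for w in workers]
    for i in range(spec.job_stream_length):
        start = date(spec.year, 1, 1) + timedelta(days=int(day_offsets[i]))
        crew = int(min(crew_sizes[i], len(worker_ids)))
        if adversarial and dose_lookup is not None:
            ranked = sorted(
                worker_ids, key=lambda w: (-dose_lookup(w, start), w)
            )
            chosen = ranked[:crew]
        else:
            idx = np.floor(worker_u[i] * len(worker_ids)).astype(int)
            chosen = list(dict.fromkeys(worker_ids[j] for j in idx))[:crew]
        yield Job(
            job_id=f"J{i:05d}",
            site_id=sites[int(site_picks[i])].site_id,
            start_date=start,
            duration=float(durations[i]),
            assigned_worker_ids=tuple(chosen),
        )


def adversarial_job_stream(
    spec: ScenarioSpec,
    scenario: Scenario,
    dose_lookup: Callable[[str, date], float] | None = None,
) -> Iterator[Job]:
    """Job proposals that maximise pressure on the dose ceiling.

    With ``dose_lookup`` (ledger-aware mode) each job targets the currently
    most-exposed workers; the lookup is consulted lazily at yield time so it
    sees doses as the consumer plans jobs.  Without it, only the
    duration/site pairing is hostile.
    """
    rng = np.random.default_rng([spec.rng_seed, 1])
    return _job_stream(
        spec, scenario.sites, scenario.workers, rng,
        adversarial=True, dose_lookup=dose_lookup,
    )


def plain_job_stream(spec: ScenarioSpec, scenario: Scenario) -> Iterator[Job]:
    """The non-adversarial stream with the same seed (for comparisons)."""
    rng = np.random.default_rng([spec.rng_seed, 1])
    return _job_stream(
        spec, scenario.sites, scenario.workers, rng,
        adversarial=False, dose_lookup=None,
    )
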