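"""Planning workflow: availability, rejection, edits, suggestions."""

from __future__ import annotations

import itertools
import math
from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from radondose import (
    DoseEntry,
    DoseLimitError,
    DoseParameters,
    InfeasibleError,
    Job,
    JobState,
    PlanningBlockedError,
    ValidationError,
    Worker,
    job_increment,
    recompute_ledger,
)
from radondose.fixtures import ScenarioSpec, adversarial_job_stream, generate_scenario
from radondose.registry import sorted_entries

from conftest import make_job, make_planner, make_site

YEAR_DAY = date(2025, 3, 1)


def credit(planner, worker_id: str, dose: float, job_id: str = "H1") -> None:
    """Put a historical dose on a worker's ledger (bypassing the planner)."""
    planner.ledger.append(
        DoseEntry(
            entry_id=f"{job_id}:{worker_id}",
            worker_id=worker_id,
            job_id=job_id,
            dose=dose,
            attribution_year=YEAR_DAY.year,
            job_date=date(2025, 1, 15),
        )
    )


def half_msv_hours(concentration: float, params: DoseParameters) -> float:
    """Duration whose dose at ``concentration`` is 0.5 mSv (to fp precision)."""
    return 0.5 / (concentration * params.dose_coefficient)


class TestJobIncrement:
    def test_half_millisievert_job(self, params):
        # 373.134... Bq/m³ × 200 h × 6.7e-6 = 0.5 mSv by hand multiplication
        conc = 0.5 / (200 * params.dose_coefficient)
        site = make_site("S1", concentration=conc)
        job = make_job(hours=200.0)
        assert job_increment(job, site, params) == pytest.approx(0.5, rel=1e-12)

    def test_increment_independent_of_crew_size(self, params):
        site = make_site("S1", concentration=400.0)
        solo = make_job(hours=10.0, workers=("W1",))
        trio = make_job(hours=10.0, workers=("W1", "W2", "W3"))
        assert job_increment(solo, site, params) == job_increment(trio, site, params)

    def test_small_duration_gives_small_increment(self, params):
        site = make_site("S1", concentration=400.0)
        inc = job_increment(make_job(hours=1e-9), site, params)
        assert 0 < inc < 1e-10

    def test_invalid_measurement_blocks_planning(self, params):
        site = make_site("S1", span_days=30)
        with pytest.raises(PlanningBlockedError):
            job_increment(make_job(hours=8.0), site, params)

    def test_zero_duration_violates_job_invariant(self):
        with pytest.raises(ValidationError):
            make_job(hours=0.0)

    def test_duplicate_assignment_violates_job_invariant(self):
        with pytest.raises(ValidationError):
            make_job(workers=("W1", "W1"))


class TestAvailableWorkers:
    def test_worker_at_5_6_not_available_for_half_msv_job(self, params, crew):
        """The worked rejection case: 5.6 accumulated + 0.5 increment > 6."""
        conc = 400.0
        planner = make_planner([make_site("S1", concentration=conc)], crew, params)
        credit(planner, "W1", 5.6)
        hours = half_msv_hours(conc, params)
        available = planner.available_workers("S1", YEAR_DAY, hours)
        ids = {w.worker_id for w in available}
        assert "W1" not in ids
        assert ids == {"W2", "W3"}

    def test_zero_dose_worker_available_for_job_up_to_ceiling(self, params, crew):
        planner = make_planner([make_site("S1", concentration=400.0)], crew, params)
        hours = 5.99 / (400.0 * params.dose_coefficient)  # just under the ceiling
        ids = {w.worker_id for w in planner.available_workers("S1", YEAR_DAY, hours)}
        assert ids == {"W1", "W2", "W3"}

    def test_total_exactly_six_is_still_available(self, crew):
        # coefficient chosen so 250 Bq/m³ × 2 h × 1e-3 is exactly 0.5 mSv in
        # floating point; 5.5 + 0.5 = 6.0 and category B is "6 mSv or less"
        params = DoseParameters(dose_coefficient=1e-3)
        planner = make_planner([make_site("S1", concentration=250.0)], crew, params)
        credit(planner, "W1", 5.5)
        ids = {w.worker_id for w in planner.available_workers("S1", YEAR_DAY, 2.0)}
        assert "W1" in ids

    def test_special_status_strict_limit(self, params):
        workers = [Worker("W1", "Ana", "pregnant"), Worker("W2", "Breogan")]
        planner = make_planner([make_site("S1", concentration=400.0)], workers, params)
        hours = 1.0 / (400.0 * params.dose_coefficient)  # exactly 1.0 mSv
        ids = {w.worker_id for w in planner.available_workers("S1", YEAR_DAY, hours)}
        assert ids == {"W2"}  # strict < 1 mSv excludes the pregnant worker

    def test_empty_result_is_legal(self, params, crew):
        planner = make_planner([make_site("S1", concentration=5000.0)], crew, params)
        hours = 7.0 / (5000.0 * params.dose_coefficient)
        assert planner.available_workers("S1", YEAR_DAY, hours) == []

    def test_monotone_in_duration(self, params, crew):
        """Longer jobs never make more workers available."""
        planner = make_planner([make_site("S1", concentration=400.0)], crew, params)
        credit(planner, "W1", 4.0)
        credit(planner, "W2", 5.5)
        rng = np.random.default_rng(5)
        durations = np.sort(rng.uniform(1, 3000, size=12))
        previous = None
        for hours in durations:
            ids = {w.worker_id for w in planner.available_workers("S1", YEAR_DAY, hours)}
            if previous is not None:
                assert ids <= previous
            previous = ids


class TestPlanJob:
    def test_worked_example_rejection_names_worker_and_keeps_ledger(self, params, crew):
        conc = 400.0
        planner = make_planner([make_site("S1", concentration=conc)], crew, params)
        credit(planner, "W1", 5.6)
        hours = half_msv_hours(conc, params)
        snapshot = sorted_entries(planner.ledger)
        job = make_job("J1", hours=hours, workers=("W1",))
        with pytest.raises(DoseLimitError) as exc:
            planner.plan_job(job)
        (violation,) = exc.value.violations
        assert violation["worker_id"] == "W1"
        assert violation["accumulated"] == pytest.approx(5.6)
        assert violation["increment"] == pytest.approx(0.5, rel=1e-12)
        assert violation["limit"] == 6.0
        # atomicity: ledger and dashboard byte-identical
        assert sorted_entries(planner.ledger) == snapshot
        assert planner.jobs == {}
        assert planner.ledger.accumulated_dose("W1", 2025) == pytest.approx(5.6)

    def test_rejection_lists_every_offending_worker(self, params, crew):
        conc = 400.0
        planner = make_planner([make_site("S1", concentration=conc)], crew, params)
        credit(planner, "W1", 5.8)
        credit(planner, "W2", 5.9, job_id="H2")
        job = make_job("J1", hours=half_msv_hours(conc, params), workers=("W1", "W2", "W3"))
        with pytest.raises(DoseLimitError) as exc:
            planner.plan_job(job)
        assert {v["worker_id"] for v in exc.value.violations} == {"W1", "W2"}

    def test_plan_success_credits_every_worker(self, params, crew):
        planner = make_planner([make_site("S1", concentration=300.0)], crew, params)
        job = make_job("J1", hours=50.0, workers=("W1", "W2"))
        planned = planner.plan_job(job)
        assert planned.state is JobState.PLANNED
        expected = 300.0 * 50.0 * params.dose_coefficient
        for wid in ("W1", "W2"):
            assert planner.ledger.accumulated_dose(wid, 2025) == expected
        assert planner.ledger.accumulated_dose("W3", 2025) == 0.0

    def test_unknown_worker_fails_plan(self, params, crew):
        planner = make_planner([make_site("S1")], crew, params)
        from radondose import NotFoundError

        with pytest.raises(NotFoundError):
            planner.plan_job(make_job("J1", workers=("W404",)))


class TestConfirmAndEdit:
    def _planner_with_job(self, params, crew, hours=100.0, conc=300.0):
        planner = make_planner(
            [make_site("S1", concentration=conc), make_site("S2", concentration=150.0)],
            crew,
            params,
        )
        planner.plan_job(make_job("J1", hours=hours, workers=("W1", "W2")))
        return planner

    def test_confirm_freezes_without_changing_doses(self, params, crew):
        planner = self._planner_with_job(params, crew)
        before = sorted_entries(planner.ledger)
        job = planner.confirm_job("J1")
        assert job.state is JobState.CONFIRMED
        assert sorted_entries(planner.ledger) == before

    def test_edit_doubling_duration_doubles_entries(self, params, crew):
        planner = self._planner_with_job(params, crew, hours=100.0)
        before = planner.ledger.accumulated_dose("W1", 2025)
        edited = planner.edit_job("J1", duration=200.0)
        assert edited.state is JobState.EDITED
        assert planner.ledger.accumulated_dose("W1", 2025) == pytest.approx(2 * before)

    def test_edit_site_swap_matches_from_scratch_rebuild(self, params, crew):
        planner = self._planner_with_job(params, crew)
        planner.edit_job("J1", site_id="S2")
        rebuilt = recompute_ledger(
            planner.jobs.values(), planner.sites, planner.workers, params
        )
        assert sorted_entries(planner.ledger) == sorted_entries(rebuilt)
        expected = 150.0 * 100.0 * params.dose_coefficient
        assert planner.ledger.accumulated_dose("W1", 2025) == pytest.approx(expected)

    def test_edit_back_to_original_is_idempotent(self, params, crew):
        planner = self._planner_with_job(params, crew, hours=100.0)
        before = sorted_entries(planner.ledger)
        planner.edit_job("J1", duration=150.0)
        planner.edit_job("J1", duration=100.0)
        assert sorted_entries(planner.ledger) == before

    def test_limit_violating_edit_refused_atomically(self, params, crew):
        conc = 400.0
        planner = make_planner([make_site("S1", concentration=conc)], crew, params)
        planner.plan_job(make_job("J1", hours=100.0, workers=("W1",)))
        credit(planner, "W1", 5.6)
        before = sorted_entries(planner.ledger)
        jobs_before = dict(planner.jobs)
        huge = 7.0 / (conc * params.dose_coefficient)
        with pytest.raises(DoseLimitError):
            planner.edit_job("J1", duration=huge)
        assert sorted_entries(planner.ledger) == before
        assert planner.jobs == jobs_before

    def test_add_worker_through_edit_credits_them(self, params, crew):
        planner = self._planner_with_job(params, crew)
        planner.edit_job("J1", add_workers=("W3",))
        assert planner.ledger.accumulated_dose("W3", 2025) > 0

    def test_unknown_job_raises(self, params, crew):
        from radondose import NotFoundError

        planner = make_planner([make_site("S1")], crew, params)
        with pytest.raises(NotFoundError):
            planner.confirm_job("J404")
        with pytest.raises(NotFoundError):
            planner.edit_job("J404", duration=5.0)


class TestSuggestAssignment:
    def test_picks_lowest_dose_workers_and_excludes_over_ceiling(self, params):
        workers = [Worker("W1", "a"), Worker("W2", "b"), Worker("W3", "c")]
        conc = 400.0
        planner = make_planner([make_site("S1", concentration=conc)], workers, params)
        credit(planner, "W2", 3.0)
        credit(planner, "W3", 5.9, job_id="H2")
        hours = 0.2 / (conc * params.dose_coefficient)  # 0.2 mSv increment
        chosen = planner.suggest_assignment("S1", YEAR_DAY, hours, 2)
        assert [w.worker_id for w in chosen] == ["W1", "W2"]  # 5.9 + 0.2 > 6

    def test_equal_doses_tie_break_lexicographic(self, params, crew):
        planner = make_planner([make_site("S1", concentration=100.0)], crew, params)
        chosen = planner.suggest_assignment("S1", YEAR_DAY, 10.0, 2)
        assert [w.worker_id for w in chosen] == ["W1", "W2"]

    def test_n_zero_gives_empty_list(self, params, crew):
        planner = make_planner([make_site("S1")], crew, params)
        assert planner.suggest_assignment("S1", YEAR_DAY, 10.0, 0) == []

    def test_infeasible_reports_available_count(self, params, crew):
        conc = 2000.0
        planner = make_planner([make_site("S1", concentration=conc)], crew, params)
        credit(planner, "W1", 5.9)
        hours = 3.0 / (conc * params.dose_coefficient)
        with pytest.raises(InfeasibleError) as exc:
            planner.suggest_assignment("S1", YEAR_DAY, hours, 3)
        assert exc.value.available == 2 and exc.value.required == 3

    def test_suggestion_always_passes_plan(self, params):
        rng = np.random.default_rng(21)
        scenario = generate_scenario(ScenarioSpec(rng_seed=21, n_workers=6, job_stream_length=0))
        planner = make_planner(scenario.sites, scenario.workers, params)
        for k in range(20):
            site = scenario.sites[int(rng.integers(len(scenario.sites)))]
            hours = float(rng.uniform(1, 60))
            try:
                chosen = planner.suggest_assignment(site.site_id, YEAR_DAY, hours, 2)
            except InfeasibleError:
                continue
            planner.plan_job(
                Job(
                    job_id=f"J{k}",
                    site_id=site.site_id,
                    start_date=YEAR_DAY,
                    duration=hours,
                    assigned_worker_ids=tuple(w.worker_id for w in chosen),
                )
            )

    def test_greedy_minimises_max_post_job_dose_vs_exhaustive(self, params):
        """On every ≤12-worker instance the greedy pick matches exhaustive
        subset search for the minimal maximum post-job accumulated dose."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n_workers = int(rng.integers(3, 13))
            workers = [Worker(f"W{i:02d}", f"w{i}") for i in range(n_workers)]
            conc = float(rng.uniform(100, 900))
            planner = make_planner([make_site("S1", concentration=conc)], workers, params)
            for i, w in enumerate(workers):
                dose = float(rng.uniform(0, 5.8))
                credit(planner, w.worker_id, dose, job_id=f"H{i}")
            hours = float(rng.uniform(1, 120))
            increment = planner.increment_for("S1", hours, YEAR_DAY)
            available = planner.available_workers("S1", YEAR_DAY, hours)
            n = int(rng.integers(1, max(2, len(available) + 1)))
            if len(available) < n:
                continue
            chosen = planner.suggest_assignment("S1", YEAR_DAY, hours, n)
            acc = {
                w.worker_id: planner.ledger.accumulated_dose(w.worker_id, 2025)
                for w in available
            }
            chosen_max = max(acc[w.worker_id] for w in chosen) + increment
            best = min(
                max(acc[w.worker_id] for w in subset) + increment
                for subset in itertools.combinations(available, n)
            )
            assert math.isclose(chosen_max, best, rel_tol=1e-12, abs_tol=1e-12)


class TestNeverExceed:
    def test_adversarial_stream_never_breaches_limits(self, params):
        """The core guarantee: a hostile job stream routed through the
        planner leaves every worker within their status's limit."""
        spec = ScenarioSpec(
            rng_seed=1234, n_sites=6, n_workers=10, job_stream_length=2000
        )
        scenario = generate_scenario(spec)
        planner = make_planner(scenario.sites, scenario.workers, params)

        def lookup(worker_id, as_of):
            return planner.accumulated_for_planning(worker_id, as_of)

        rejected = 0
        for job in adversarial_job_stream(spec, scenario, dose_lookup=lookup):
            try:
                planner.plan_job(job)
            except DoseLimitError:
                rejected += 1
        assert rejected > 0  # the stream must actually pressure the ceiling
        for w in scenario.workers:
            dose = planner.ledger.accumulated_dose(w.worker_id, spec.year)
            if w.status == "standard":
                assert dose <= params.category_b_limit
            else:
                assert dose < params.special_status_limit
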