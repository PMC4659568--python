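from datetime import date

import numpy as np
import pytest

from steplink import (
    AdminIndexRecord,
    ConfigError,
    DataError,
    DEFAULT_STEPS,
    DialectError,
    DirectLinkage,
    DirectOutcome,
    MatchClassification,
    MatchStep,
    MonthMode,
    StepwiseLinkage,
    TrialRecord,
    YearMode,
    candidates,
    classify_step,
    derive_index_records,
    run_stepwise,
)
from steplink.simulate import SimConfig, simulate_pair

from _oracle import oracle_stepwise
from conftest import random_small_instance, simulate_and_match


def trec(tid="T1", site="S1", gender="M", birth=date(2000, 1, 15), enroll=date(2007, 3, 10), **kw):
    return TrialRecord(tid, site, gender, enroll, birth_date=birth, **kw)


def arec(aid="A1", site="S1", gender="M", birth=date(2000, 1, 15), adm=date(2007, 3, 22)):
    return AdminIndexRecord(aid, site, gender, adm, birth_date=birth)


STEP1, STEP2, STEP3, STEP4 = DEFAULT_STEPS


class TestStepDefinition:
    def test_default_schedule_shape(self):
        assert [s.step_number for s in DEFAULT_STEPS] == [1, 2, 3, 4]
        assert STEP1.month_mode is MonthMode.EXACT and STEP1.year_mode is YearMode.EXACT
        assert STEP2.month_mode is MonthMode.IGNORED and STEP2.year_mode is YearMode.EXACT
        assert STEP3.year_mode is YearMode.IGNORED
        assert STEP4.year_mode is YearMode.TOLERANCE and STEP4.year_tolerance == 1

    def test_shipped_yaml_reproduces_default_schedule(self):
        from steplink.steps import default_steps_path, load_steps

        assert load_steps(default_steps_path()) == DEFAULT_STEPS

    def test_month_exact_requires_year_exact(self):
        with pytest.raises(ConfigError):
            MatchStep(1, YearMode.IGNORED, MonthMode.EXACT)

    def test_duplicate_step_numbers_rejected(self):
        steps = (MatchStep(1, YearMode.EXACT, MonthMode.EXACT),) * 2
        with pytest.raises(ConfigError):
            StepwiseLinkage([], [], steps)


class TestCandidates:
    def test_all_six_agree(self):
        assert candidates(trec(), [arec()], STEP1) == {arec()}

    def test_month_difference_recovered_at_step2(self):
        a = arec(adm=date(2007, 4, 22))
        assert candidates(trec(), [a], STEP1) == set()
        assert candidates(trec(), [a], STEP2) == {a}

    @pytest.mark.parametrize("year,included", [(2008, True), (2006, True), (2009, False), (2005, False)])
    def test_step4_tolerance_is_plus_minus_one_year(self, year, included):
        a = arec(adm=date(year, 7, 22))
        assert (a in candidates(trec(), [a], STEP4)) == included

    def test_blocking_fields_always_exact(self):
        for a in (
            arec(site="S2"),
            arec(gender="F", birth=date(2000, 1, 15)),
            arec(birth=date(2000, 2, 15)),
            arec(birth=date(2001, 1, 15)),
        ):
            for step in DEFAULT_STEPS:
                assert candidates(trec(), [a], step) == set()

    def test_transfer_date_defines_trial_event(self):
        t = trec(enroll=date(2007, 3, 10), transfer_date=date(2007, 6, 1))
        a_enroll_month = arec(adm=date(2007, 3, 15))
        a_transfer_month = arec(aid="A2", adm=date(2007, 6, 20))
        assert candidates(t, [a_enroll_month, a_transfer_month], STEP1) == {a_transfer_month}

    def test_missing_field_yields_empty_set(self):
        t = trec(gender=None)
        assert candidates(t, [arec()], STEP3) == set()


class TestClassifyStep:
    def test_unique(self):
        sr = classify_step([trec()], [arec()], STEP1)
        assert sr.classifications["T1"] is MatchClassification.UNIQUE
        assert sr.assignments == {"T1": "A1"}

    def test_two_admin_candidates_is_multiple_admin(self):
        pool = [arec(aid="A1"), arec(aid="A2")]
        sr = classify_step([trec()], pool, STEP1)
        assert sr.classifications["T1"] is MatchClassification.MULTIPLE_ADMIN

    def test_shared_sole_candidate_is_multiple_trial_for_all(self):
        avail = [trec(tid="T1"), trec(tid="T2")]
        sr = classify_step(avail, [arec()], STEP1)
        assert sr.classifications["T1"] is MatchClassification.MULTIPLE_TRIAL
        assert sr.classifications["T2"] is MatchClassification.MULTIPLE_TRIAL
        assert sr.assignments == {}

    def test_forward_ambiguity_takes_precedence(self):
        # T1 has two candidates -> MULTIPLE_ADMIN even though T2 contests A1
        avail = [trec(tid="T1"), trec(tid="T2")]
        pool = [arec(aid="A1"), arec(aid="A2")]
        sr = classify_step(avail, pool, STEP1)
        assert sr.classifications["T1"] is MatchClassification.MULTIPLE_ADMIN
        assert sr.classifications["T2"] is MatchClassification.MULTIPLE_ADMIN

    def test_partition_identity(self):
        rng = np.random.default_rng(5)
        trial, admin = random_small_instance(rng)
        sr = classify_step(trial, admin, STEP2)
        assert sr.n_available == sr.n_unique + sr.n_no_match + sr.n_multiple_admin + sr.n_multiple_trial

    def test_missing_field_classified_no_match_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            sr = classify_step([trec(gender=None)], [arec()], STEP1)
        assert sr.classifications["T1"] is MatchClassification.NO_MATCH
        assert "missing a matching field" in caplog.text


class TestRunStepwise:
    def test_worked_fixture_hand_trace(self, worked, worked_result):
        _, _, _, expected = worked
        res = worked_result
        for sr in res.step_results:
            assert sorted(sr.assignments) == expected["unique_per_step"][sr.step_number]
        for (tid, step), cls in expected["classifications"].items():
            got = dict((s, c.value) for s, c, _ in res.trace[tid])
            assert got[step] == cls, (tid, step)
        assert res.final_assignments == expected["final_assignments"]
        assert [sr.n_available for sr in res.step_results] == expected["n_available_per_step"]
        assert res.n_unique_cumulative == expected["cumulative_unique"]

    def test_empty_admin_pool(self):
        res = run_stepwise([trec(tid="T1"), trec(tid="T2", gender="F")], [])
        for sr in res.step_results:
            assert sr.n_no_match == sr.n_available == 2
        assert res.final_assignments == {}

    def test_carry_forward_identity(self, worked_result):
        srs = worked_result.step_results
        for prev, nxt in zip(srs, srs[1:]):
            assert nxt.n_available == prev.n_available - prev.n_unique

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        trial, admin = random_small_instance(rng)
        res1 = run_stepwise(trial, admin)
        res2 = run_stepwise(trial[::-1], admin[::-1])
        assert res1.final_assignments == res2.final_assignments
        assert [sr.classifications for sr in res1.step_results] == [
            sr.classifications for sr in res2.step_results
        ]

    def test_final_assignments_injective(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            trial, admin = random_small_instance(rng)
            res = run_stepwise(trial, admin)
            vals = list(res.final_assignments.values())
            assert len(set(vals)) == len(vals)

    def test_duplicate_trial_ids_rejected(self):
        with pytest.raises(DataError):
            run_stepwise([trec(), trec()], [])

    def test_duplicate_admin_ids_rejected(self):
        with pytest.raises(DataError):
            run_stepwise([], [arec(), arec(adm=date(2008, 1, 1))])

    def test_symmetry_under_side_swap(self):
        # all comparisons are symmetric, so exchanging the roles of the two
        # tables must produce the same linked pairs
        rng = np.random.default_rng(37)
        for _ in range(10):
            trial, admin = random_small_instance(rng)
            fwd = run_stepwise(trial, admin).final_assignments
            # swap roles: admin patients become "trial" records and vice versa
            as_trial = [
                TrialRecord(
                    a.admin_id, a.site_id, a.gender, a.admission_date,
                    birth_year=a.birth_year, birth_month=a.birth_month,
                )
                for a in admin
            ]
            as_admin = []
            for t in trial:
                ev = t.transfer_date or t.enrollment_date
                as_admin.append(
                    AdminIndexRecord(
                        t.trial_id, t.site_id, t.gender, ev,
                        birth_year=t.birth_year, birth_month=t.birth_month,
                    )
                )
            rev = run_stepwise(as_trial, as_admin).final_assignments
            assert {(t, a) for t, a in fwd.items()} == {(t, a) for a, t in rev.items()}


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(60):
            trial, admin = random_small_instance(rng)
            res = run_stepwise(trial, admin)
            oracle_steps, oracle_final = oracle_stepwise(trial, admin, DEFAULT_STEPS)
            assert res.final_assignments == oracle_final
            for sr, expected in zip(res.step_results, oracle_steps):
                got = {tid: c.value for tid, c in sr.classifications.items()}
                assert got == expected


class TestCandidateMonotonicity:
    def test_step_nesting_and_no_match_persistence(self):
        # per record: candidates(step1) <= step2 <= step4 <= step3, hence a
        # step-3 NO_MATCH can never match at step 4
        rng = np.random.default_rng(99)
        for _ in range(40):
            trial, admin = random_small_instance(rng)
            for t in trial:
                c1 = {a.admin_id for a in candidates(t, admin, STEP1)}
                c2 = {a.admin_id for a in candidates(t, admin, STEP2)}
                c3 = {a.admin_id for a in candidates(t, admin, STEP3)}
                c4 = {a.admin_id for a in candidates(t, admin, STEP4)}
                assert c1 <= c2 <= c4 <= c3
                if not c3:
                    assert not c4


class TestDirectMerge:
    def test_unique_match(self):
        res = DirectLinkage([trec()], [arec()]).fit()
        assert res.outcomes["T1"] == (DirectOutcome.UNIQUE, frozenset({"A1"}))
        assert res.assignments == {"T1": "A1"}

    def test_duplicate_admin_dobs(self):
        pool = [arec(aid="A1"), arec(aid="A2", adm=date(2009, 9, 9))]
        res = DirectLinkage([trec()], pool).fit()
        kind, ids = res.outcomes["T1"]
        assert kind is DirectOutcome.DUPLICATES and ids == frozenset({"A1", "A2"})

    def test_no_match(self):
        res = DirectLinkage([trec()], [arec(birth=date(2000, 1, 16))]).fit()
        assert res.outcomes["T1"][0] is DirectOutcome.NO_MATCH

    def test_contested_candidate_is_multiple_trial(self):
        res = DirectLinkage([trec(tid="T1"), trec(tid="T2")], [arec()]).fit()
        assert res.outcomes["T1"][0] is DirectOutcome.MULTIPLE_TRIAL
        assert res.outcomes["T2"][0] is DirectOutcome.MULTIPLE_TRIAL

    def test_dob_only_matching_ignores_event_dates(self):
        # same DOB/site/gender but admission far from enrollment still matches
        res = DirectLinkage([trec()], [arec(adm=date(2010, 1, 1))]).fit()
        assert res.outcomes["T1"][0] is DirectOutcome.UNIQUE

    def test_indirect_only_dialect_refused(self):
        t = TrialRecord("T1", "S1", "M", date(2007, 1, 1), birth_year=2000, birth_month=1)
        with pytest.raises(DialectError, match="indirect-only"):
            DirectLinkage([t], [arec()])
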