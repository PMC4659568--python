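from datetime import date

import numpy as np
import pytest

from steplink import (
    ConfigError,
    MatchClassification,
    derive_index_records,
    evaluate_against_truth,
    filter_aml_cohort,
)
from steplink.cohort import is_aml_code
from steplink.records import effective_event_date
from steplink.simulate import SimConfig, make_worked_fixture, simulate_pair

from conftest import simulate_and_match

SMALL = dict(n_trial=80, n_sites=10, n_distractors=30)


class TestGenerator:
    def test_determinism_same_seed(self):
        cfg = SimConfig(seed=42, **SMALL)
        assert simulate_pair(cfg) == simulate_pair(cfg)

    def test_distinct_seeds_differ(self):
        a = simulate_pair(SimConfig(seed=1, **SMALL))
        b = simulate_pair(SimConfig(seed=2, **SMALL))
        assert a != b

    def test_capture_accounting(self):
        cfg = SimConfig(n_trial=100, p_captured=0.6, p_readmission=0.0, seed=3)
        trial, admissions, truth = simulate_pair(cfg)
        n_captured = sum(1 for v in truth.values() if v is not None)
        assert len(trial) == 100
        assert set(truth) == {t.trial_id for t in trial}
        # admissions = captured patients + distractors (one admission each)
        assert len(admissions) == n_captured + cfg.n_distractors
        # capture count ~ Binomial(100, 0.6): within a generous band
        assert 40 <= n_captured <= 80

    def test_truth_ids_exist_in_tables(self):
        trial, admissions, truth = simulate_pair(SimConfig(seed=4, **SMALL))
        admin_ids = {a.admin_id for a in admissions}
        for tid, aid in truth.items():
            if aid is not None:
                assert aid in admin_ids

    def test_all_admissions_qualify_and_lie_in_window(self):
        cfg = SimConfig(seed=5, **SMALL)
        _, admissions, _ = simulate_pair(cfg)
        assert filter_aml_cohort(admissions, cfg.window) == admissions
        assert all(any(is_aml_code(c) for c in a.icd9_codes) for a in admissions)

    def test_noise_free_six_tuples_identical(self):
        cfg = SimConfig(
            p_captured=1.0, p_gross_error=0.0, p_collision=0.0,
            admission_lag_days=(0, 0), seed=6, **SMALL
        )
        trial, admissions, truth = simulate_pair(cfg)
        by_id = {a.admin_id: a for a in derive_index_records(admissions)}
        for t in trial:
            a = by_id[truth[t.trial_id]]
            ev = effective_event_date(t)
            assert (t.site_id, t.gender, t.birth_year, t.birth_month) == (
                a.site_id, a.gender, a.birth_year, a.birth_month
            )
            assert (ev.year, ev.month) == (a.admission_date.year, a.admission_date.month)

    def test_transfer_dates_present_at_requested_rate(self):
        trial, _, _ = simulate_pair(SimConfig(p_transfer=0.5, seed=7, **SMALL))
        n = sum(1 for t in trial if t.transfer_date is not None)
        assert 20 <= n <= 60

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_sites=0),
            dict(p_captured=1.5),
            dict(admission_lag_days=(5, 2)),
            dict(birth_year_range=(2000, 2020)),  # births after window start
            dict(n_trial=100000, n_sites=1, birth_year_range=(2000, 2001)),  # key space too small
        ],
    )
    def test_infeasible_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            simulate_pair(SimConfig(**bad))


class TestNoiseModel:
    def test_step1_recovers_captured_set_without_noise(self):
        cfg = SimConfig(
            p_captured=0.7, p_gross_error=0.0, p_collision=0.0,
            admission_lag_days=(0, 0), seed=8, **SMALL
        )
        _, _, truth, res = simulate_and_match(cfg)
        n_captured = sum(1 for v in truth.values() if v is not None)
        assert res.step_results[0].n_unique == n_captured
        m = evaluate_against_truth(res, truth)
        assert m.sensitivity == 1.0 and m.ppv == 1.0

    def test_gross_error_degrades_step1_but_later_steps_recover(self):
        base = dict(p_captured=0.8, p_collision=0.0, seed=9, **SMALL)
        _, _, _, clean = simulate_and_match(SimConfig(p_gross_error=0.0, **base))
        _, _, truth, noisy = simulate_and_match(SimConfig(p_gross_error=0.4, **base))
        assert noisy.step_results[0].n_unique <= clean.step_results[0].n_unique
        # the cascade exists to recover those losses
        assert noisy.n_unique_cumulative > noisy.step_results[0].n_unique
        assert evaluate_against_truth(noisy, truth).ppv == 1.0

    def test_injected_identical_keys_never_unique(self):
        # force heavy collisions with no other noise; colliding six-tuples
        # must surface as MULTIPLE_ADMIN or MULTIPLE_TRIAL, never UNIQUE
        # a one-month window makes every event share year/month, so an
        # injected blocking-key collision is a full six-tuple collision
        cfg = SimConfig(
            n_trial=60, n_sites=3, n_distractors=40, p_captured=1.0,
            p_gross_error=0.0, p_collision=0.5, admission_lag_days=(0, 0),
            p_transfer=0.0, window=(date(2007, 3, 1), date(2007, 3, 28)), seed=10,
        )
        trial, index, truth, res = simulate_and_match(cfg)
        keys = {}
        for t in trial:
            k = (t.site_id, t.gender, t.birth_year, t.birth_month,
                 t.enrollment_date.year, t.enrollment_date.month)
            keys.setdefault(k, []).append(t.trial_id)
        dup_tids = {tid for tids in keys.values() if len(tids) > 1 for tid in tids}
        assert dup_tids, "collision injection produced no identical six-tuples"
        for tid in dup_tids:
            for _, cls, _ in res.trace[tid]:
                assert cls is not MatchClassification.UNIQUE


class TestWorkedFixture:
    def test_expectation_is_internally_consistent(self):
        trial, admissions, truth, expected = make_worked_fixture()
        assert len(trial) == 5
        assert expected["cumulative_unique"] == 4
        assert expected["cumulative_unique_pct"] == 80.0
        assert set(expected["final_assignments"]) == {t for t, v in truth.items() if v}

    def test_repeat_admission_present_for_index_derivation(self):
        _, admissions, _, _ = make_worked_fixture()
        ids = [a.admin_id for a in admissions]
        assert ids.count("PD") == 2
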