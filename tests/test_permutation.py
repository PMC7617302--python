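"""The permutational algorithm: weights, sequential sampling, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from _oracles import enumerate_assignment_probs
from survsim_qba import (
    Cohort,
    OutcomePool,
    RiskSetExhaustedError,
    TrueHazardModel,
    TVEPanel,
    assign_censorings,
    assign_events,
    generate_oracle,
    hazard_ratio_at,
)
from survsim_qba.permutation import assign_all_outcomes, static_log_weights


class TestHazardRatioAt:
    def test_null_model_is_one(self):
        model = TrueHazardModel(log_hr_exposure=0.0)
        assert hazard_ratio_at(model, {"exposure": 1}) == 1.0
        assert hazard_ratio_at(model, {"exposure": 0}) == 1.0

    def test_exposure_only(self):
        model = TrueHazardModel(log_hr_exposure=np.log(2))
        assert hazard_ratio_at(model, {"exposure": 1}) == pytest.approx(2.0)

    def test_tve_model_with_age_and_sex(self):
        # exposed 70-year-old man under HRs 1.5 (exposure), 1.066/yr, 1.098 (male)
        model = TrueHazardModel(
            log_hr_exposure=np.log(1.5),
            covariate_log_hrs={"age": np.log(1.066), "male": np.log(1.098)},
            tve_flag=True,
        )
        panel = TVEPanel(subject_id=1, daily=np.array([0, 1, 1]), follow_up_end=3)
        expected = 1.5 * 1.066**70 * 1.098
        got = hazard_ratio_at(model, {"age": 70, "male": 1}, t=2, panel=panel)
        assert got == pytest.approx(expected, rel=1e-12)
        # unexposed on day 1
        assert hazard_ratio_at(model, {"age": 70, "male": 1}, t=1, panel=panel) == pytest.approx(
            expected / 1.5, rel=1e-12
        )

    def test_unknown_covariate_errors(self):
        model = TrueHazardModel(log_hr_exposure=0.0, covariate_log_hrs={"bmi": 0.1})
        with pytest.raises(KeyError):
            hazard_ratio_at(model, {"exposure": 0})

    def test_day_beyond_panel_errors(self):
        model = TrueHazardModel(log_hr_exposure=0.1, tve_flag=True)
        panel = TVEPanel(subject_id=1, daily=np.array([1, 0]), follow_up_end=2)
        with pytest.raises(ValueError):
            hazard_ratio_at(model, {}, t=3, panel=panel)


class TestAssignEvents:
    def test_first_draw_proportional_to_weights(self):
        # weights {1, 2, 1} -> selection probabilities {0.25, 0.5, 0.25}
        rng = np.random.default_rng(0)
        counts = np.zeros(3)
        for _ in range(20_000):
            a = assign_events(np.array([1.0]), np.array([1.0, 2.0, 1.0]), 3, rng)
            counts[a.assignee[0]] += 1
        freq = counts / counts.sum()
        assert np.abs(freq - [0.25, 0.5, 0.25]).max() < 0.015

    def test_singleton_risk_set(self):
        rng = np.random.default_rng(1)
        a = assign_events(np.array([2.0]), np.array([5.0]), 1, rng)
        assert a.assignee[0] == 0

    def test_null_model_orderings_equiprobable(self):
        # uniform weights, 4 subjects, 4 events: all 4! assignments equally likely
        rng = np.random.default_rng(2)
        times = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.ones(4)
        counts: dict[tuple, int] = {}
        n_draws = 40_000
        for _ in range(n_draws):
            a = assign_events(times, w, 4, rng)
            key = tuple(a.assignee)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 24
        expected = n_draws / 24
        se = np.sqrt(n_draws * (1 / 24) * (1 - 1 / 24))
        for c in counts.values():
            assert abs(c - expected) < 4 * se

    def test_weighted_frequencies_match_enumeration(self):
        # sequential weighted sampling vs brute-force enumeration, chi-square
        w = np.array([1.0, 2.0, 3.0, 0.5])
        times = np.array([1.0, 2.0, 3.0])
        exact = enumerate_assignment_probs(w, times)
        rng = np.random.default_rng(3)
        n_draws = 100_000
        counts = {k: 0 for k in exact}
        for _ in range(n_draws):
            a = assign_events(times, w, 4, rng)
            counts[tuple(a.assignee)] += 1
        observed = np.array([counts[k] for k in exact])
        expected = n_draws * np.array([exact[k] for k in exact])
        assert expected.sum() == pytest.approx(n_draws)
        _, p = chisquare(observed, expected)
        assert p > 0.001

    def test_admissibility_restricts_risk_set(self):
        # subject 0 leaves follow-up at day 4: event at 5 can only go to subject 1
        rng = np.random.default_rng(4)
        admissible = np.array([4.0, 10.0])
        for _ in range(20):
            a = assign_events(np.array([5.0]), np.ones(2), 2, rng, admissible_until=admissible)
            assert a.assignee[0] == 1

    def test_exhausted_risk_set_errors(self):
        rng = np.random.default_rng(5)
        with pytest.raises(RiskSetExhaustedError):
            assign_events(
                np.array([5.0, 6.0]), np.ones(2), 2, rng, admissible_until=np.array([4.0, 5.5])
            )

    def test_nonfinite_weight_errors(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            assign_events(np.array([1.0]), np.array([1.0, np.inf]), 2, rng)


class TestAssignCensorings:
    def test_deterministic_single_match(self):
        subjects, times = assign_censorings(
            np.array([7.0]), np.array([3]), np.random.default_rng(0)
        )
        assert subjects.tolist() == [3] and times.tolist() == [7.0]

    def test_count_mismatch_errors(self):
        with pytest.raises(ValueError):
            assign_censorings(np.array([1.0, 2.0]), np.array([0]), np.random.default_rng(0))

    def test_two_by_two_matchings_uniform(self):
        rng = np.random.default_rng(7)
        hits = 0
        n = 10_000
        for _ in range(n):
            _, times = assign_censorings(np.array([5.0, 9.0]), np.array([0, 1]), rng)
            hits += times[0] == 5.0
        assert abs(hits / n - 0.5) < 0.02

    def test_multiset_preserved(self):
        rng = np.random.default_rng(8)
        times_in = np.linspace(1, 50, 17)
        _, times_out = assign_censorings(times_in, np.arange(17), rng)
        assert sorted(times_out) == pytest.approx(sorted(times_in))


class TestAssignAllOutcomes:
    def test_conservation_and_census(self, toy_pool):
        time, status = assign_all_outcomes(toy_pool, np.ones(5), np.random.default_rng(0))
        pooled = np.sort(np.concatenate([toy_pool.event_times, toy_pool.censoring_times]))
        assert np.sort(time) == pytest.approx(pooled)
        assert status.sum() == toy_pool.n_events

    def test_censored_subject_never_gets_later_event(self):
        # a subject assigned the censoring time 2.0 must be out of the risk
        # set for the event at 6.0: generation and analysis risk sets agree
        pool = OutcomePool(event_times=np.array([6.0]), censoring_times=np.array([2.0]))
        rng = np.random.default_rng(1)
        for _ in range(50):
            time, status = assign_all_outcomes(pool, np.array([1.0, 1.0]), rng)
            censored = int(np.flatnonzero(status == 0)[0])
            assert time[censored] == 2.0
            assert time[1 - censored] == 6.0

    def test_null_model_uniform_over_outcome_permutations(self):
        # with equal weights the joint process is an exchangeable permutation
        # of outcomes over subjects
        pool = OutcomePool(event_times=np.array([1.0, 4.0]), censoring_times=np.array([2.0]))
        rng = np.random.default_rng(2)
        counts: dict[tuple, int] = {}
        n = 30_000
        for _ in range(n):
            time, status = assign_all_outcomes(pool, np.ones(3), rng)
            counts[tuple(time)] = counts.get(tuple(time), 0) + 1
        assert len(counts) == 6
        expected = n / 6
        se = np.sqrt(n * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - expected) < 4 * se

    def test_count_mismatch_errors(self, toy_pool):
        with pytest.raises(ValueError):
            assign_all_outcomes(toy_pool, np.ones(7), np.random.default_rng(0))


class TestGenerateOracle:
    def test_conservation_permute_all(self, toy_cohort, toy_pool):
        model = TrueHazardModel(log_hr_exposure=np.log(2), covariate_log_hrs={"z": 0.3})
        ds = generate_oracle(toy_cohort, model, toy_pool, np.random.default_rng(0))
        pooled = np.sort(np.concatenate([toy_pool.event_times, toy_pool.censoring_times]))
        assert np.sort(ds.frame["time"].to_numpy()) == pytest.approx(pooled)
        assert ds.n_events == toy_pool.n_events
        # every subject has exactly one outcome
        assert len(ds.frame) == toy_cohort.n

    def test_fixed_censoring_keeps_follow_up(self, toy_cohort):
        pool = OutcomePool(event_times=np.array([3.0, 5.0]), censoring_times=np.array([]))
        follow_up = np.array([10.0, 4.0, 10.0, 2.0, 6.0])
        model = TrueHazardModel(log_hr_exposure=0.0)
        ds = generate_oracle(
            toy_cohort, model, pool, np.random.default_rng(1),
            mode="fixed_censoring", follow_up_end=follow_up,
        )
        censored = ds.frame[ds.frame["status"] == 0]
        for row in censored.itertuples():
            i = int(np.flatnonzero(toy_cohort.ids == row.id)[0])
            assert row.time == follow_up[i]
        events = ds.frame[ds.frame["status"] == 1]
        for row in events.itertuples():
            i = int(np.flatnonzero(toy_cohort.ids == row.id)[0])
            assert row.time <= follow_up[i]

    def test_single_subject_gets_event(self):
        cohort = Cohort(
            ids=np.array([1]), exposure=np.array([1]), covariates=pd.DataFrame({"z": [0.0]})
        )
        pool = OutcomePool(event_times=np.array([4.0]), censoring_times=np.array([]))
        model = TrueHazardModel(log_hr_exposure=1.0, covariate_log_hrs={"z": 0.0})
        ds = generate_oracle(cohort, model, pool, np.random.default_rng(0))
        assert ds.frame["status"].tolist() == [1]
        assert ds.frame["time"].tolist() == [4.0]

    def test_static_weights_match_pointwise_hazard(self, toy_cohort):
        model = TrueHazardModel(log_hr_exposure=0.4, covariate_log_hrs={"z": -0.2})
        w = np.exp(static_log_weights(model, toy_cohort))
        for i in range(toy_cohort.n):
            subject = {"exposure": toy_cohort.exposure[i], "z": toy_cohort.covariates["z"].iloc[i]}
            assert w[i] == pytest.approx(hazard_ratio_at(model, subject))
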