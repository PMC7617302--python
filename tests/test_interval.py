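"""True-time draws, imputation rules and the TVE oracle construction."""

import numpy as np
import pytest
from scipy.stats import chisquare

from survsim_qba import (
    EventInterval,
    Scenario,
    build_imperfect_tve,
    build_oracle_tve,
    draw_true_event_time,
    impute_endpoint,
    impute_midpoint,
    redistribute_event_times,
)
from survsim_qba.interval import observed_dataset


class TestDrawTrueEventTime:
    def test_support_and_uniformity_small(self):
        iv = EventInterval(s=0, tau=10, delta=3)
        rng = np.random.default_rng(0)
        draws = np.array([draw_true_event_time(iv, rng) for _ in range(30_000)])
        assert set(draws) == {8, 9, 10}
        freq = np.bincount(draws)[8:]
        _, p = chisquare(freq)
        assert p > 0.001

    def test_degenerate_interval_deterministic(self):
        iv = EventInterval(s=0, tau=42, delta=1)
        rng = np.random.default_rng(1)
        assert {draw_true_event_time(iv, rng) for _ in range(10)} == {42}

    def test_long_interval_mean_and_uniformity(self):
        # uniform on {11, ..., 100}: mean (11 + 100) / 2 = 55.5
        iv = EventInterval(s=0, tau=100, delta=90)
        rng = np.random.default_rng(2)
        draws = np.array([draw_true_event_time(iv, rng) for _ in range(100_000)])
        assert draws.min() >= 11 and draws.max() <= 100
        assert draws.mean() == pytest.approx(55.5, abs=0.3)
        _, p = chisquare(np.bincount(draws)[11:])
        assert p > 0.001


class TestImputation:
    @pytest.mark.parametrize(
        "tau, delta, expected",
        [(100, 30, 85), (10, 3, 8), (10, 1, 10), (11, 1, 11), (180, 90, 135)],
    )
    def test_midpoint(self, tau, delta, expected):
        assert impute_midpoint(EventInterval(s=0, tau=tau, delta=delta)) == expected

    @pytest.mark.parametrize("tau, delta", [(100, 30), (10, 3), (7, 1)])
    def test_endpoint_is_reporting_visit(self, tau, delta):
        assert impute_endpoint(EventInterval(s=0, tau=tau, delta=delta)) == tau

    @pytest.mark.parametrize("tau", [50, 51])
    @pytest.mark.parametrize("delta", range(1, 12))
    def test_ordering_and_bounds(self, tau, delta):
        iv = EventInterval(s=0, tau=tau, delta=delta)
        mid, end = impute_midpoint(iv), impute_endpoint(iv)
        assert mid <= end
        assert tau - iv.delta + 1 <= mid <= tau


class TestBuildOracleTVE:
    def test_event_count_conserved(self, benzo_small):
        sc = Scenario(name="hr2", true_hr_exposure=2.0)
        ds = build_oracle_tve(benzo_small, sc, np.random.default_rng(0))
        assert ds.n_events == benzo_small.n_events
        assert len(ds.table) == benzo_small.n

    def test_unassigned_keep_follow_up_end(self, benzo_small):
        sc = Scenario(name="hr1", true_hr_exposure=1.0)
        ds = build_oracle_tve(benzo_small, sc, np.random.default_rng(1))
        cens = ds.table[ds.table["status"] == 0]
        ends = {s: benzo_small.panels[s].follow_up_end for s in benzo_small.ids}
        assert all(row.time == ends[row.id] for row in cens.itertuples())

    def test_reporting_visit_brackets_true_time(self, benzo_small):
        sc = Scenario(name="hr15", true_hr_exposure=1.5)
        ds = build_oracle_tve(benzo_small, sc, np.random.default_rng(2))
        ev = ds.table[ds.table["status"] == 1]
        for row in ev.itertuples():
            assert row.tau - row.delta < row.time <= row.tau
            assert row.tau in benzo_small.visits[row.id]

    def test_exposed_overrepresented_when_hr_high(self, benzo_small):
        # at assignment the exposed share among assignees should exceed the
        # exposed share of the whole risk set when the exposure HR is large
        X = benzo_small.exposure_matrix()
        sc = Scenario(name="hr", true_hr_exposure=8.0)
        assigned_exposed = risk_exposed = 0
        for seed in range(10):
            ds = build_oracle_tve(benzo_small, sc, np.random.default_rng(200 + seed))
            ev = ds.table[ds.table["status"] == 1]
            pos = {sid: i for i, sid in enumerate(benzo_small.ids)}
            for row in ev.itertuples():
                day = int(row.time)
                assigned_exposed += int(X[pos[row.id], day - 1])
                risk_exposed += float(X[:, day - 1].mean())
        assert assigned_exposed > risk_exposed

    def test_null_model_ignores_exposure(self, benzo_small):
        # under HR=1 assignment probabilities do not depend on the panel,
        # only on age/sex weights; two cohorts differing only in panels give
        # identical assignments for the same seed
        sc = Scenario(name="hr1", true_hr_exposure=1.0)
        ds1 = build_oracle_tve(benzo_small, sc, np.random.default_rng(5))
        ds2 = build_oracle_tve(benzo_small, sc, np.random.default_rng(5))
        assert ds1.table.equals(ds2.table)


class TestBuildImperfectTVE:
    def test_midpoint_and_endpoint_times(self, benzo_small):
        sc = Scenario(name="hr15", true_hr_exposure=1.5)
        oracle = build_oracle_tve(benzo_small, sc, np.random.default_rng(3))
        mid = build_imperfect_tve(oracle, "midpoint")
        end = build_imperfect_tve(oracle, "endpoint")
        ev = oracle.table["status"] == 1
        for o, m, e in zip(
            oracle.table[ev].itertuples(), mid.table[ev].itertuples(), end.table[ev].itertuples()
        ):
            iv = EventInterval(s=0, tau=int(o.tau), delta=int(o.delta))
            assert m.time == impute_midpoint(iv)
            assert e.time == impute_endpoint(iv)
        # censorings untouched
        assert mid.table.loc[~ev, "time"].equals(oracle.table.loc[~ev, "time"])

    def test_unknown_strategy_errors(self, benzo_small):
        sc = Scenario(name="hr15", true_hr_exposure=1.5)
        oracle = build_oracle_tve(benzo_small, sc, np.random.default_rng(4))
        with pytest.raises(ValueError):
            build_imperfect_tve(oracle, "left")


class TestRedistributeEventTimes:
    def test_event_count_and_subjects_preserved(self, benzo_small):
        ds = redistribute_event_times(benzo_small, np.random.default_rng(6))
        assert ds.n_events == benzo_small.n_events
        ev_ids = set(ds.table.loc[ds.table["status"] == 1, "id"])
        assert ev_ids == set(benzo_small.event_subjects)

    def test_times_inside_own_intervals(self, benzo_small):
        ds = redistribute_event_times(benzo_small, np.random.default_rng(7))
        iv_by_subject = dict(zip(benzo_small.event_subjects, benzo_small.event_intervals))
        for row in ds.table[ds.table["status"] == 1].itertuples():
            iv = iv_by_subject[row.id]
            assert iv.tau - iv.delta + 1 <= row.time <= iv.tau

    def test_width_one_intervals_unchanged(self, benzo_small):
        ds = redistribute_event_times(benzo_small, np.random.default_rng(8))
        obs = observed_dataset(benzo_small)
        one_day = obs.table["delta"] == 1
        if one_day.any():
            assert ds.table.loc[one_day, "time"].equals(obs.table.loc[one_day, "time"])
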