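"""Interval-censored events with a time-varying exposure (Example-2 studies).

The observed data report each event only at a clinic visit ``tau``, so the true
event day is known only to lie in the preceding between-visits window of
``delta`` days. The oracle construction draws a true day uniformly in that
window, assigns it to a subject via the permutational algorithm (weights using
the subject's daily exposure value on that day), and censors everyone else at
their original follow-up end. Imperfect datasets re-impute the assigned events
at the midpoint or the endpoint (detection visit) of the assignee's own
between-visits interval, reproducing the measurement process of the real data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import EventInterval, Scenario, TrueHazardModel, TVECohort, TVEDataset
from .permutation import assign_events

__all__ = [
    "draw_true_event_time",
    "impute_midpoint",
    "impute_endpoint",
    "build_oracle_tve",
    "build_imperfect_tve",
    "observed_dataset",
    "redistribute_event_times",
]


def draw_true_event_time(interval: EventInterval, rng: np.random.Generator) -> int:
    """Uniform integer day in ``{tau - delta + 1, ..., tau}`` (probability 1/delta each)."""
    return int(rng.integers(interval.tau - interval.delta + 1, interval.tau + 1))


def impute_midpoint(interval: EventInterval) -> int:
    """Midpoint of the between-visits interval, in whole days.

    ``tau - delta/2`` with half-days rounded toward the earlier day, then
    clipped into the admissible event window ``[tau - delta + 1, tau]`` (the
    clip only matters for one-day intervals, where the event day is known
    exactly and the midpoint is the visit day itself).
    """
    mid = int(np.floor(interval.tau - interval.delta / 2))
    return max(mid, interval.tau - interval.delta + 1)


def impute_endpoint(interval: EventInterval) -> int:
    """Detection-visit imputation: the visit day ``tau`` at which the event was reported."""
    return interval.tau


def build_oracle_tve(
    tve_cohort: TVECohort,
    scenario: Scenario,
    rng: np.random.Generator,
    covariate_log_hrs: dict[str, float] | None = None,
) -> TVEDataset:
    """One oracle dataset for the time-varying-exposure design.

    Steps, consuming the generator in a fixed order:

    1. draw a true day ``T_s`` uniformly within each observed event interval;
    2. assign each ``T_s`` to one subject by weighted sampling with weights
       ``exp(b_x * X_i(T_s) + covariate terms)``, restricted to subjects whose
       original follow-up reaches ``T_s`` and who have no event yet;
    3. record the assignee's own reporting visit (first visit at or after
       ``T_s``) and interval length for later re-imputation;
    4. censor every unassigned subject at their original follow-up end.
    """
    model = TrueHazardModel(
        log_hr_exposure=scenario.true_log_hr,
        covariate_log_hrs=dict(covariate_log_hrs or {}),
        tve_flag=True,
    )
    true_times = np.array(
        [draw_true_event_time(iv, rng) for iv in tve_cohort.event_intervals], dtype=float
    )

    X = tve_cohort.exposure_matrix()
    static = np.zeros(tve_cohort.n)
    for name, beta in model.covariate_log_hrs.items():
        if name not in tve_cohort.subjects.columns:
            raise KeyError(f"unknown covariate {name!r}")
        static += beta * tve_cohort.subjects[name].to_numpy(dtype=float)
    static_w = np.exp(static)
    bx = np.exp(model.log_hr_exposure)

    def weights_at(t: float) -> np.ndarray:
        day = int(t)
        return static_w * np.where(X[:, day - 1] == 1, bx, 1.0)

    follow_up = tve_cohort.follow_up_end.astype(float)
    assignment = assign_events(
        true_times, weights_at, tve_cohort.n, rng, admissible_until=follow_up
    )

    ids = tve_cohort.ids
    time = follow_up.copy()
    status = np.zeros(tve_cohort.n, dtype=int)
    tau = np.full(tve_cohort.n, np.nan)
    delta = np.full(tve_cohort.n, np.nan)
    for t, i in zip(assignment.event_times, assignment.assignee):
        t_day = int(t)
        r_tau, r_delta = tve_cohort.reporting_visit(ids[i], t_day)
        time[i] = t_day
        status[i] = 1
        tau[i] = r_tau
        delta[i] = r_delta

    table = pd.DataFrame(
        {"id": ids, "time": time.astype(int), "status": status, "tau": tau, "delta": delta}
    )
    return TVEDataset(cohort=tve_cohort, table=table)


def build_imperfect_tve(oracle: TVEDataset, strategy: str) -> TVEDataset:
    """Replace true event days by midpoint- or endpoint-imputed days.

    Censoring times and the exposure panels are untouched; analyses of the
    imperfect dataset simply look exposure up at the imputed day.
    """
    if strategy not in ("midpoint", "endpoint"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    impute = impute_midpoint if strategy == "midpoint" else impute_endpoint
    table = oracle.table.copy()
    is_event = table["status"] == 1
    new_times = []
    for row in table.loc[is_event].itertuples(index=False):
        iv = EventInterval(s=0, tau=int(row.tau), delta=int(row.delta))
        end = oracle.cohort.panels[row.id].follow_up_end
        day = impute(iv)
        if day > end:
            raise ValueError(f"imputed event day {day} after last visit of {row.id}")
        new_times.append(day)
    table.loc[is_event, "time"] = new_times
    return TVEDataset(cohort=oracle.cohort, table=table)


def observed_dataset(tve_cohort: TVECohort) -> TVEDataset:
    """The original data as a one-row-per-subject table.

    Events are placed at their reporting visit (endpoint) with their interval
    recorded, censored subjects at their follow-up end; feed through
    :func:`build_imperfect_tve` to obtain the midpoint-imputed version.
    """
    ids = tve_cohort.ids
    time = tve_cohort.follow_up_end.astype(int)
    status = np.zeros(tve_cohort.n, dtype=int)
    tau = np.full(tve_cohort.n, np.nan)
    delta = np.full(tve_cohort.n, np.nan)
    pos = {sid: i for i, sid in enumerate(ids)}
    for iv, sid in zip(tve_cohort.event_intervals, tve_cohort.event_subjects):
        i = pos[sid]
        time[i] = iv.tau
        status[i] = 1
        tau[i] = iv.tau
        delta[i] = iv.delta
    table = pd.DataFrame({"id": ids, "time": time, "status": status, "tau": tau, "delta": delta})
    return TVEDataset(cohort=tve_cohort, table=table)


def redistribute_event_times(tve_cohort: TVECohort, rng: np.random.Generator) -> TVEDataset:
    """Sensitivity analysis: move each observed event, keeping its subject.

    Each observed event is relocated to a uniformly random day within its own
    between-visits interval; censored subjects are untouched. Unlike the
    oracle construction, no true model is imposed — this emulates a QBA-style
    perturbation of the original data only.
    """
    ids = tve_cohort.ids
    time = tve_cohort.follow_up_end.astype(int)
    status = np.zeros(tve_cohort.n, dtype=int)
    tau = np.full(tve_cohort.n, np.nan)
    delta = np.full(tve_cohort.n, np.nan)
    pos = {sid: i for i, sid in enumerate(ids)}
    for iv, sid in zip(tve_cohort.event_intervals, tve_cohort.event_subjects):
        i = pos[sid]
        time[i] = draw_true_event_time(iv, rng)
        status[i] = 1
        tau[i] = iv.tau
        delta[i] = iv.delta
    table = pd.DataFrame({"id": ids, "time": time, "status": status, "tau": tau, "delta": delta})
    return TVEDataset(cohort=tve_cohort, table=table)
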