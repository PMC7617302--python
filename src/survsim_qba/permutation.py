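"""The permutational algorithm for data-driven survival simulation.

Observed outcome times are reassigned to observed covariate/exposure vectors so
that a user-specified proportional-hazards model becomes the true
data-generating model, while the marginal distribution of outcome times is kept
exactly equal to the data at hand. Event times are processed in increasing
order; the event at time ``t`` is assigned to one subject from the current risk
set, drawn with probability proportional to the subject's model hazard ratio
``HR_i(t)``, and the assignee is removed from all future risk sets.

Two modes reflect the two study designs supported by the package:

* ``permute_all`` — every observed outcome (event or censoring) is reassigned;
  after all events are placed, censoring times are matched uniformly at random
  to the remaining subjects, producing a bijection between outcomes and
  subjects.
* ``fixed_censoring`` — only events are reassigned, constrained so that an
  event at time ``t`` may only go to a subject whose own follow-up extends to
  ``t``; subjects left without an event keep their original follow-up end as a
  censoring time.

Within one Monte-Carlo repetition all stochastic steps consume a single seeded
``numpy.random.Generator`` in a fixed order (tie shuffling, then the sequential
event draws, then censoring matching), so repetitions are exactly reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, OutcomePool, SurvivalDataset, TrueHazardModel, TVEPanel

__all__ = [
    "Assignment",
    "RiskSetExhaustedError",
    "hazard_ratio_at",
    "static_log_weights",
    "assign_events",
    "assign_censorings",
    "assign_all_outcomes",
    "generate_oracle",
]


class RiskSetExhaustedError(RuntimeError):
    """Raised when no admissible subject remains for some event time.

    Signals that the admissibility constraints (e.g. original follow-up ends in
    ``fixed_censoring`` mode) are incompatible with the observed event times.
    """


@dataclass
class Assignment:
    """Event-to-subject map produced by the sequential weighted sampling.

    ``event_times[k]`` was assigned to subject index ``assignee[k]`` (positions
    refer to the processing order, events sorted by time with ties shuffled).
    """

    event_times: np.ndarray
    assignee: np.ndarray

    def __post_init__(self) -> None:
        if len(np.unique(self.assignee)) != len(self.assignee):
            raise ValueError("each subject may be assigned at most one event")


def hazard_ratio_at(
    model: TrueHazardModel,
    subject: Mapping[str, float],
    t: int | None = None,
    panel: TVEPanel | None = None,
) -> float:
    """Hazard ratio ``HR_i(t)`` of one subject under the true model.

    ``subject`` maps variable names (``"exposure"``, covariates, optionally the
    confounder) to values. For a time-varying exposure the value on day ``t``
    is looked up in ``panel``; otherwise the constant ``subject["exposure"]``
    is used.
    """
    if model.tve_flag:
        if panel is None or t is None:
            raise ValueError("time-varying model requires a panel and a day t")
        x = panel.exposure_at(t)
    else:
        x = float(subject["exposure"])
    lp = model.log_hr_exposure * x
    for name, beta in model.covariate_log_hrs.items():
        if name not in subject:
            raise KeyError(f"unknown covariate {name!r}")
        lp += beta * float(subject[name])
    if model.log_hr_confounder is not None:
        lp += model.log_hr_confounder * float(subject[model.confounder_name])
    return float(np.exp(lp))


def static_log_weights(
    model: TrueHazardModel,
    cohort: Cohort,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Vector of time-invariant log hazard ratios for a whole cohort.

    For a time-varying model this is the time-invariant part of the linear
    predictor (covariates and confounder); the exposure term is added per day
    by the caller.
    """
    lp = np.zeros(cohort.n)
    if not model.tve_flag:
        lp += model.log_hr_exposure * np.asarray(cohort.exposure, dtype=float)
    for name, beta in model.covariate_log_hrs.items():
        if name not in cohort.covariates.columns:
            raise KeyError(f"unknown covariate {name!r}")
        lp += beta * cohort.covariates[name].to_numpy(dtype=float)
    if model.log_hr_confounder is not None:
        if confounder is None:
            if model.confounder_name in cohort.covariates.columns:
                confounder = cohort.covariates[model.confounder_name].to_numpy()
            else:
                raise ValueError("model has a confounder term but no values supplied")
        lp += model.log_hr_confounder * np.asarray(confounder, dtype=float)
    return lp


def _processing_order(event_times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of events in increasing time order, ties in random order."""
    perm = rng.permutation(len(event_times))
    return perm[np.argsort(event_times[perm], kind="stable")]


def assign_events(
    event_times: np.ndarray,
    weights_at: Callable[[float], np.ndarray] | np.ndarray,
    n_subjects: int,
    rng: np.random.Generator,
    admissible_until: np.ndarray | None = None,
) -> Assignment:
    """Sequential weighted sampling of one subject per event time.

    Parameters
    ----------
    event_times
        Observed event times (any order; processed ascending, ties shuffled).
    weights_at
        Either a fixed vector of per-subject hazard ratios (time-invariant
        models) or a callable ``t -> vector`` evaluated fresh at each event
        time (time-varying exposure).
    n_subjects
        Cohort size.
    rng
        Seeded generator; consumed in a documented fixed order.
    admissible_until
        Optional per-subject last admissible event day: subject ``i`` is in the
        risk set at time ``t`` only while ``admissible_until[i] >= t`` (used in
        ``fixed_censoring`` mode where original follow-up ends are kept).

    Raises
    ------
    RiskSetExhaustedError
        If no admissible, still-unassigned subject remains at some event time.
    ValueError
        If any sampling weight is nonfinite or nonpositive.
    """
    times = np.asarray(event_times, dtype=float)
    order = _processing_order(times, rng)
    static = not callable(weights_at)
    if static:
        w_full = np.asarray(weights_at, dtype=float)
        _check_weights(w_full)

    alive = np.ones(n_subjects, dtype=bool)
    assignee = np.empty(len(times), dtype=int)
    for k in order:
        t = times[k]
        eligible = alive if admissible_until is None else alive & (admissible_until >= t)
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            raise RiskSetExhaustedError(f"empty risk set at event time {t}")
        w = w_full[idx] if static else np.asarray(weights_at(t), dtype=float)[idx]
        if not static:
            _check_weights(w)
        chosen = idx[rng.choice(idx.size, p=w / w.sum())]
        assignee[k] = chosen
        alive[chosen] = False
    return Assignment(event_times=times, assignee=assignee)


def _check_weights(w: np.ndarray) -> None:
    if not np.isfinite(w).all():
        raise ValueError("nonfinite sampling weight")
    if (w <= 0).any():
        raise ValueError("sampling weights must be positive")


def assign_censorings(
    censoring_times: np.ndarray,
    unassigned_subjects: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random one-to-one matching of censoring times to subjects.

    Returns ``(subjects, times)`` aligned pairwise. Requires exactly as many
    censoring times as remaining subjects (the permute-all design).
    """
    times = np.asarray(censoring_times, dtype=float)
    subjects = np.asarray(unassigned_subjects)
    if len(times) != len(subjects):
        raise ValueError(
            f"{len(times)} censoring times but {len(subjects)} unassigned subjects"
        )
    perm = rng.permutation(len(times))
    return subjects, times[perm]


def assign_all_outcomes(
    pool: OutcomePool,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly assign every pooled outcome in increasing time order.

    Events are assigned by weighted sampling proportional to the hazard-ratio
    weights; censoring times are assigned uniformly at random from the same
    shrinking risk set (censoring is taken independent of covariates). Either
    way the assignee leaves all future risk sets, so a subject censored at
    time ``t`` can never receive a later event — the risk sets of the
    generating process coincide exactly with the risk sets a Cox fit of the
    oracle dataset will use. Returns per-subject ``(time, status)``.
    """
    n = len(weights)
    times = np.concatenate([pool.event_times, pool.censoring_times]).astype(float)
    is_event = np.concatenate(
        [np.ones(pool.n_events, dtype=bool), np.zeros(pool.n_censorings, dtype=bool)]
    )
    if len(times) != n:
        raise ValueError("permute_all requires one pooled outcome per subject")
    _check_weights(weights)
    order = _processing_order(times, rng)
    alive = np.ones(n, dtype=bool)
    time = np.empty(n)
    status = np.zeros(n, dtype=int)
    for k in order:
        idx = np.flatnonzero(alive)
        if is_event[k]:
            w = weights[idx]
            chosen = idx[rng.choice(idx.size, p=w / w.sum())]
        else:
            chosen = idx[rng.integers(idx.size)]
        time[chosen] = times[k]
        status[chosen] = int(is_event[k])
        alive[chosen] = False
    return time, status


def generate_oracle(
    cohort: Cohort,
    model: TrueHazardModel,
    pool: OutcomePool,
    rng: np.random.Generator,
    mode: str = "permute_all",
    follow_up_end: np.ndarray | None = None,
    censoring_mode: str = "joint",
) -> SurvivalDataset:
    """Generate one oracle dataset for a time-invariant exposure design.

    In ``permute_all`` mode every pooled outcome (event or censoring) is
    reassigned, so the outcome-time multiset of the oracle equals the pool
    exactly. Censorings are assigned jointly with the events in time order
    (``censoring_mode="joint"``, the validated variant) or matched uniformly
    to the leftover subjects after all events are placed
    (``censoring_mode="matched"``, kept for comparison; it lets subjects that
    would already be censored compete for later events and induces a small
    bias when the model is non-null). In ``fixed_censoring`` mode only events
    are assigned (subject to ``follow_up_end`` admissibility) and unassigned
    subjects keep their original follow-up end as censoring time.
    """
    if mode not in ("permute_all", "fixed_censoring"):
        raise ValueError(f"unknown mode {mode!r}")
    if censoring_mode not in ("joint", "matched"):
        raise ValueError(f"unknown censoring_mode {censoring_mode!r}")
    if mode == "permute_all" and pool.n_events + pool.n_censorings != cohort.n:
        raise ValueError("permute_all requires one pooled outcome per subject")
    if mode == "fixed_censoring" and follow_up_end is None:
        raise ValueError("fixed_censoring mode requires follow_up_end")

    weights = np.exp(static_log_weights(model, cohort))
    if mode == "permute_all" and censoring_mode == "joint":
        time, status = assign_all_outcomes(pool, weights, rng)
    else:
        assignment = assign_events(
            pool.event_times,
            weights,
            cohort.n,
            rng,
            admissible_until=follow_up_end if mode == "fixed_censoring" else None,
        )
        time = np.empty(cohort.n)
        status = np.zeros(cohort.n, dtype=int)
        time[assignment.assignee] = assignment.event_times
        status[assignment.assignee] = 1
        unassigned = np.flatnonzero(status == 0)
        if mode == "permute_all":
            subjects, times = assign_censorings(pool.censoring_times, unassigned, rng)
            time[subjects] = times
        else:
            time[unassigned] = np.asarray(follow_up_end, dtype=float)[unassigned]

    frame = pd.DataFrame({"id": cohort.ids, "exposure": cohort.exposure})
    for c in cohort.covariate_names:
        frame[c] = cohort.covariates[c].to_numpy()
    frame["time"] = time
    frame["status"] = status
    return SurvivalDataset(frame=frame)
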