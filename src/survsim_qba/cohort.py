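"""Core domain types for survival cohorts and their tabular formats.

The package works with two kinds of study populations:

* a classic one-row-per-subject cohort (binary exposure, baseline covariates,
  follow-up time, event status), and
* a longitudinal cohort with a daily binary time-varying exposure (TVE) panel,
  a schedule of clinic visits, and interval-censored events known only to have
  occurred between two adjacent visits.

Time is measured in whole days since cohort entry (day 1 is the first day of
follow-up); counting-process intervals are half-open ``(start, stop]`` with the
event attributed to ``stop``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "OutcomePool",
    "EventInterval",
    "TVEPanel",
    "TVECohort",
    "TrueHazardModel",
    "ConfounderSpec",
    "Scenario",
    "SurvivalDataset",
    "TVEDataset",
    "SubjectTable",
    "read_subject_table",
    "read_tve_cohort",
    "write_counting_process",
    "read_counting_process",
]

_NA_TOKENS = {"", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class Cohort:
    """Immutable collection of per-subject covariate/exposure vectors.

    Parameters
    ----------
    ids
        Opaque subject identifiers, one per subject.
    exposure
        Binary (0/1) exposure indicator per subject.
    covariates
        Numeric covariate matrix, one row per subject; column names are the
        covariate names (identical for every subject by construction).
    """

    ids: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise ValueError("no subjects")
        if len(self.exposure) != n or len(self.covariates) != n:
            raise ValueError("ids, exposure and covariates must have equal length")
        exp = np.asarray(self.exposure)
        if not np.isin(exp, [0, 1]).all():
            raise ValueError("exposure must be binary 0/1")
        vals = self.covariates.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("covariate values must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def with_covariate(self, name: str, values: np.ndarray) -> "Cohort":
        """Return a new cohort with one extra covariate column appended."""
        cov = self.covariates.copy()
        cov[name] = np.asarray(values)
        return Cohort(self.ids, self.exposure, cov)


@dataclass(frozen=True)
class OutcomePool:
    """Multiset of observed outcome times, split into events and censorings.

    The pool is extracted once from the source data and then reused across
    Monte-Carlo repetitions: the permutational algorithm reassigns these exact
    times to subjects, so the marginal outcome-time distribution of every
    simulated dataset matches the data at hand.
    """

    event_times: np.ndarray
    censoring_times: np.ndarray

    def __post_init__(self) -> None:
        for arr, label in ((self.event_times, "event"), (self.censoring_times, "censoring")):
            a = np.asarray(arr, dtype=float)
            if a.size and (a <= 0).any():
                raise ValueError(f"nonpositive {label} times")

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def n_censorings(self) -> int:
        return len(self.censoring_times)


@dataclass(frozen=True)
class EventInterval:
    """An interval-censored event: reported at visit day ``tau``, known to have
    occurred in the ``delta`` days ``{tau - delta + 1, ..., tau}``."""

    s: int
    tau: int
    delta: int

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("interval length delta must be >= 1")
        if self.tau - self.delta < 0:
            raise ValueError("interval start tau - delta must be >= 0")


@dataclass(frozen=True)
class TVEPanel:
    """Daily binary exposure panel for one subject.

    ``daily[d - 1]`` is the exposure indicator on day ``d`` (day 1 = first day
    of follow-up, e.g. the first prescription in a new-user design).
    """

    subject_id: object
    daily: np.ndarray
    follow_up_end: int

    def __post_init__(self) -> None:
        d = np.asarray(self.daily)
        if not np.isin(d, [0, 1]).all():
            raise ValueError(f"panel values must be 0/1 for subject {self.subject_id}")
        if len(d) < self.follow_up_end:
            raise ValueError(
                f"panel for subject {self.subject_id} shorter than follow-up end"
            )
        if self.follow_up_end < 1:
            raise ValueError("follow_up_end must be >= 1")

    def exposure_at(self, day: int) -> int:
        if not 1 <= day <= len(self.daily):
            raise ValueError(f"day {day} outside panel for subject {self.subject_id}")
        return int(self.daily[day - 1])


class TVECohort:
    """Longitudinal cohort with daily exposure panels and clinic visits.

    Parameters
    ----------
    subjects
        One row per subject with columns ``id`` plus baseline covariates
        (``age`` in years and a ``male`` indicator for the drug-exposure
        example) and ``follow_up_end`` (day of last follow-up visit).
    panels
        Mapping subject id -> :class:`TVEPanel`.
    visits
        Mapping subject id -> sorted array of visit days (cohort entry, day 0,
        is implicit and not listed).
    event_intervals
        One :class:`EventInterval` per observed event.
    event_subjects
        Subject id that reported each interval, aligned with
        ``event_intervals`` (used only by sensitivity analyses that keep the
        observed event-to-subject pairing).
    """

    def __init__(
        self,
        subjects: pd.DataFrame,
        panels: Mapping[object, TVEPanel],
        visits: Mapping[object, np.ndarray],
        event_intervals: Sequence[EventInterval],
        event_subjects: Sequence[object],
    ) -> None:
        if len(event_intervals) != len(event_subjects):
            raise ValueError("event_intervals and event_subjects must align")
        self.subjects = subjects.reset_index(drop=True)
        self.panels = dict(panels)
        self.visits = {k: np.asarray(v, dtype=int) for k, v in visits.items()}
        self.event_intervals = list(event_intervals)
        self.event_subjects = list(event_subjects)
        self._validate()
        # run-length encoding of each panel, cached for fast counting-process
        # construction: (change_days, values) with change_days[0] == 1
        self._rle: dict[object, tuple[np.ndarray, np.ndarray]] = {}

    def _validate(self) -> None:
        ids = set(self.subjects["id"])
        for sid in ids:
            if sid not in self.panels:
                raise ValueError(f"missing exposure panel for subject {sid}")
            v = self.visits.get(sid)
            if v is None or len(v) == 0:
                raise ValueError(f"subject {sid} has no follow-up visits")
            end = self.panels[sid].follow_up_end
            if (v < 1).any() or (v > end).any():
                raise ValueError(f"visit days outside follow-up for subject {sid}")
        for iv, sid in zip(self.event_intervals, self.event_subjects):
            prev = iv.tau - iv.delta
            v = self.visits[sid]
            if iv.tau not in v:
                raise ValueError(f"event visit {iv.tau} not a recorded visit of {sid}")
            if prev != 0 and prev not in v:
                raise ValueError(
                    f"interval start {prev} is neither a visit of {sid} nor cohort entry"
                )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return len(self.event_intervals)

    @property
    def ids(self) -> np.ndarray:
        return self.subjects["id"].to_numpy()

    @property
    def follow_up_end(self) -> np.ndarray:
        return np.array([self.panels[s].follow_up_end for s in self.ids])

    def exposure_matrix(self) -> np.ndarray:
        """(n, max_day) uint8 matrix of daily exposures, zero-padded."""
        max_day = max(len(self.panels[s].daily) for s in self.ids)
        X = np.zeros((self.n, max_day), dtype=np.uint8)
        for i, sid in enumerate(self.ids):
            d = self.panels[sid].daily
            X[i, : len(d)] = d
        return X

    def panel_rle(self, sid: object) -> tuple[np.ndarray, np.ndarray]:
        """Run-length encoding (start days, values) of a subject's panel."""
        if sid not in self._rle:
            d = np.asarray(self.panels[sid].daily, dtype=np.int8)
            change = np.flatnonzero(np.diff(d)) + 1  # 0-based index of new run
            starts = np.concatenate(([1], change + 1))
            values = d[np.concatenate(([0], change))]
            self._rle[sid] = (starts, values)
        return self._rle[sid]

    def reporting_visit(self, sid: object, day: int) -> tuple[int, int]:
        """First visit at or after ``day`` and the interval length before it.

        Returns ``(tau, delta)`` where ``tau`` is the subject's first visit at
        or after ``day`` and ``delta = tau - previous visit`` (cohort entry,
        day 0, counts as the previous visit for the first interval).
        """
        v = self.visits[sid]
        pos = int(np.searchsorted(v, day, side="left"))
        if pos >= len(v):
            raise ValueError(f"no visit of subject {sid} at or after day {day}")
        tau = int(v[pos])
        prev = int(v[pos - 1]) if pos > 0 else 0
        return tau, tau - prev


@dataclass(frozen=True)
class TrueHazardModel:
    """User-defined proportional-hazards data-generating model.

    The model supplies, for each subject ``i`` and day ``t``, the hazard ratio

    ``HR_i(t) = exp(b_x * x_i(t) + b_s * s_i + sum_c b_c * c_i)``

    relative to a baseline subject, used by the permutational algorithm as the
    sampling weight at each event time. Exposure may be constant
    (``tve_flag=False``) or looked up in the subject's daily panel.
    """

    log_hr_exposure: float
    covariate_log_hrs: Mapping[str, float] = field(default_factory=dict)
    log_hr_confounder: float | None = None
    confounder_name: str = "stage"
    tve_flag: bool = False

    def __post_init__(self) -> None:
        vals = [self.log_hr_exposure, *self.covariate_log_hrs.values()]
        if self.log_hr_confounder is not None:
            vals.append(self.log_hr_confounder)
        if not np.all(np.isfinite(vals)):
            raise ValueError("all log hazard ratios must be finite")


@dataclass(frozen=True)
class ConfounderSpec:
    """Generative assumptions for a simulated binary confounder."""

    target_prevalence: float = 0.35
    or_exposure: float = 1.2
    or_covariates: Mapping[str, float] = field(default_factory=dict)
    hr_outcome: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.or_exposure <= 0 or self.hr_outcome <= 0:
            raise ValueError("odds/hazard ratios must be > 0")


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: a true exposure effect plus the assumptions
    that define the imperfection under study."""

    name: str
    true_hr_exposure: float
    confounder: ConfounderSpec | None = None
    strategies: tuple[str, ...] | None = None
    m: int | None = None
    base_seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_hr_exposure <= 0:
            raise ValueError("true exposure HR must be > 0")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def true_log_hr(self) -> float:
        return float(np.log(self.true_hr_exposure))


@dataclass
class SurvivalDataset:
    """One simulated (oracle or imperfect) one-row-per-subject dataset."""

    frame: pd.DataFrame

    @property
    def n_events(self) -> int:
        return int(self.frame["status"].sum())


@dataclass
class TVEDataset:
    """One simulated dataset for the time-varying-exposure design.

    ``table`` has one row per subject: ``id``, outcome ``time`` (day), event
    ``status``, and for events the reporting visit ``tau`` and interval length
    ``delta`` of the subject the event was assigned to.
    """

    cohort: TVECohort
    table: pd.DataFrame

    @property
    def n_events(self) -> int:
        return int(self.table["status"].sum())

    def to_counting_process(self) -> pd.DataFrame:
        """Expand to start-stop format with one row per constant-exposure run.

        Intervals are half-open ``(start, stop]``; the exposure on row
        ``(start, stop]`` applies to days ``start+1 .. stop``, so the value in
        effect at an event day ``t`` is the panel value on day ``t`` itself.
        """
        sub = self.cohort.subjects.set_index("id")
        baseline_cols = [c for c in sub.columns if c != "follow_up_end"]
        out: list[tuple] = []
        for row in self.table.itertuples(index=False):
            sid, t_end, status = row.id, int(row.time), int(row.status)
            starts, values = self.cohort.panel_rle(sid)
            keep = starts <= t_end
            s, v = starts[keep], values[keep]
            stops = np.append(s[1:] - 1, t_end).astype(int)
            base = tuple(sub.loc[sid, c] for c in baseline_cols)
            for k in range(len(s)):
                ev = status if k == len(s) - 1 else 0
                out.append((sid, int(s[k] - 1), int(stops[k]), ev, int(v[k])) + base)
        return pd.DataFrame(
            out, columns=["id", "start", "stop", "event", "exposure"] + baseline_cols
        )


@dataclass
class SubjectTable:
    """Result of reading a one-row-per-subject survival table."""

    cohort: Cohort
    pool: OutcomePool
    frame: pd.DataFrame
    n_dropped: int


def read_subject_table(
    path,
    *,
    id_col: str = "id",
    exposure_col: str = "exposure",
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: Sequence[str] | None = None,
) -> SubjectTable:
    """Read a delimited one-row-per-subject survival table.

    Applies a complete-case filter on the declared analysis columns (exposure,
    covariates, time, status); the number of dropped rows is logged and
    returned. Raises on missing columns, non-binary status or nonpositive
    follow-up times.
    """
    df = pd.read_csv(path, na_values=list(_NA_TOKENS), keep_default_na=False)
    required = [id_col, exposure_col, time_col, status_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in required]
    else:
        absent = [c for c in covariate_cols if c not in df.columns]
        if absent:
            raise ValueError(f"missing covariate columns: {absent}")

    analysis = [exposure_col, *covariate_cols, time_col, status_col]
    complete = df.dropna(subset=analysis).reset_index(drop=True)
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, len(df))
    if complete.empty:
        raise ValueError("no subjects")

    status = complete[status_col].to_numpy()
    if not np.isin(status, [0, 1]).all():
        raise ValueError("status must be binary 0/1")
    times = complete[time_col].to_numpy(dtype=float)
    if (times <= 0).any():
        raise ValueError("nonpositive follow-up times")

    cohort = Cohort(
        ids=complete[id_col].to_numpy(),
        exposure=complete[exposure_col].to_numpy(dtype=int),
        covariates=complete[list(covariate_cols)].astype(float),
    )
    pool = OutcomePool(
        event_times=times[status == 1], censoring_times=times[status == 0]
    )
    frame = complete.rename(
        columns={id_col: "id", exposure_col: "exposure", time_col: "time", status_col: "status"}
    )
    return SubjectTable(cohort=cohort, pool=pool, frame=frame, n_dropped=n_dropped)


def read_tve_cohort(subject_path, panel_path, visit_path) -> TVECohort:
    """Assemble a :class:`TVECohort` from three CSV tables.

    ``subject_path``: one row per subject (``id``, baseline covariates,
    ``follow_up_end``). ``panel_path``: long table (``id``, ``day``,
    ``exposure``) covering every day 1..follow_up_end. ``visit_path``: long
    table (``id``, ``day``, ``event``) of clinic visits with an event-reported
    flag.
    """
    subjects = pd.read_csv(subject_path)
    panel = pd.read_csv(panel_path)
    visits_df = pd.read_csv(visit_path)
    for df, cols, label in (
        (subjects, ["id", "follow_up_end"], "subject"),
        (panel, ["id", "day", "exposure"], "panel"),
        (visits_df, ["id", "day", "event"], "visit"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{label} table missing columns: {missing}")

    panels: dict[object, TVEPanel] = {}
    for sid, grp in panel.groupby("id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=int)
        end = int(subjects.loc[subjects["id"] == sid, "follow_up_end"].iloc[0])
        expected = np.arange(1, end + 1)
        if len(days) < end or not np.array_equal(days[:end], expected):
            raise ValueError(f"panel gaps before follow-up end for subject {sid}")
        panels[sid] = TVEPanel(
            subject_id=sid,
            daily=grp["exposure"].to_numpy(dtype=int),
            follow_up_end=end,
        )

    visits: dict[object, np.ndarray] = {}
    intervals: list[EventInterval] = []
    event_subjects: list[object] = []
    s = 0
    for sid, grp in visits_df.groupby("id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=int)
        visits[sid] = days
        for day, ev in zip(days, grp["event"].to_numpy(dtype=int)):
            if ev:
                pos = int(np.searchsorted(days, day))
                prev = int(days[pos - 1]) if pos > 0 else 0
                intervals.append(EventInterval(s=s, tau=int(day), delta=int(day) - prev))
                event_subjects.append(sid)
                s += 1
    return TVECohort(subjects, panels, visits, intervals, event_subjects)


def write_counting_process(dataset: TVEDataset, path) -> None:
    """Write a simulated TVE dataset as a counting-process (start-stop) CSV."""
    long_df = dataset.to_counting_process()
    _check_no_overlap(long_df)
    long_df.to_csv(path, index=False)


def read_counting_process(path) -> pd.DataFrame:
    """Read a counting-process CSV and validate interval structure."""
    df = pd.read_csv(path)
    _check_no_overlap(df)
    return df


def _check_no_overlap(df: pd.DataFrame) -> None:
    for sid, grp in df.groupby("id", sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        stops = g["stop"].to_numpy()
        if (stops <= starts).any() or (starts[1:] < stops[:-1]).any():
            raise ValueError(f"overlapping counting-process intervals for subject {sid}")
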