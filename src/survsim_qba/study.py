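"""Study objects orchestrating the full simulation workflow.

The two model classes mirror the statsmodels pattern: a study object is built
from data plus simulation assumptions, its ``fit()`` runs the Monte-Carlo
repetitions (oracle generation, imperfection, model fits) and returns a
:class:`QBAResults` carrying per-repetition estimates, per-scenario performance
summaries, paired model comparisons and a ``summary()`` table.

Reproducibility: repetition ``r`` of a scenario uses a generator seeded from
``SeedSequence([base_seed, crc32(scenario name), r])``, so results are
independent of scenario execution order and identical across reruns; all
analysis models of a repetition share the same simulated dataset, which is
what makes the paired "closer to the truth" comparison meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, ConfounderSpec, OutcomePool, Scenario, TVECohort
from .confounder import make_imperfect_confounder, make_oracle_with_stage
from .estimation import (
    EstimateRecord,
    cox_coefficients,
    cox_tve_coefficients,
    fit_cox,
    fit_cox_tve,
)
from .interval import (
    build_imperfect_tve,
    build_oracle_tve,
    observed_dataset,
    redistribute_event_times,
)
from .performance import ComparisonSummary, PerformanceSummary, compare_models, summarize

logger = logging.getLogger(__name__)

__all__ = [
    "ConfounderBiasStudy",
    "IntervalCensoringStudy",
    "QBAResults",
    "table1_scenarios",
    "table2_scenarios",
]

_EST_COLS = ["scenario", "rep", "model", "log_hr", "se", "ci_low", "ci_high", "converged", "n_events"]


def _rep_rng(base_seed: int, scenario_name: str, rep: int) -> np.random.Generator:
    """Child generator for one repetition: stable hash of (seed, scenario, rep).

    Keying on the scenario *name* makes results independent of scenario
    execution order and safe under parallel execution."""
    tag = zlib.crc32(scenario_name.encode())
    return np.random.default_rng(np.random.SeedSequence([base_seed, tag, rep]))


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class QBAResults:
    """Results of a fitted simulation study.

    ``estimates`` holds one row per (scenario, repetition, analysis model);
    ``summaries`` maps (scenario name, model label) to a
    :class:`PerformanceSummary`; ``comparisons`` maps scenario name to the
    paired comparison of the two imputation models where applicable.
    """

    estimates: pd.DataFrame
    summaries: dict[tuple[str, str], PerformanceSummary]
    comparisons: dict[str, ComparisonSummary] = field(default_factory=dict)
    baseline: dict[str, EstimateRecord] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Performance measures as a table with one row per scenario x model."""
        rows = []
        for (scenario, model), s in self.summaries.items():
            row = {"scenario": scenario, "model": model, **s.to_dict()}
            cmp = self.comparisons.get(scenario)
            if cmp is not None and model == sorted({m for sc, m in self.summaries if sc == scenario})[0]:
                row.update(cmp.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def comparison_frame(self) -> pd.DataFrame:
        rows = [{"scenario": sc, **c.to_dict()} for sc, c in self.comparisons.items()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table (log-HR scale)."""
        df = self.summary_frame()
        cols = [
            "scenario", "model", "true_log_hr", "m_used", "bias", "relative_bias_pct",
            "empirical_se", "rmse", "coverage", "rejection_rate",
        ]
        out = ["Quantitative bias analysis — Monte-Carlo performance (log HR scale)", ""]
        with pd.option_context("display.float_format", lambda v: f"{v:8.3f}"):
            out.append(df[cols].to_string(index=False))
        if self.comparisons:
            out += ["", "Paired comparison (endpoint over midpoint):"]
            out.append(self.comparison_frame().to_string(index=False))
        return "\n".join(out)

    def save(self, outdir) -> None:
        """Write summary.csv, estimates.csv and provenance.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out / "summary.csv", index=False)
        self.estimates.to_csv(out / "estimates.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))


class ConfounderBiasStudy:
    """Quantify the impact of an unmeasured binary confounder on a Cox fit.

    Built from a one-row-per-subject cohort; each repetition simulates the
    confounder, reassigns all pooled outcomes with the permutational algorithm
    under the scenario's true model, and fits Cox models with (oracle) and
    without (imperfect) the simulated confounder.

    Parameters
    ----------
    cohort, pool
        Observed covariate vectors and outcome pool (see
        :func:`survsim_qba.cohort.read_subject_table`).
    scenarios
        Scenarios with ``confounder`` specifications.
    m
        Monte-Carlo repetitions per scenario (scenario.m overrides).
    covariate_log_hrs
        True-model log HRs of the measured covariates; default: the
        uncorrected Cox fit on the source data (requires ``frame``).
    frame
        Original subject table with ``time``/``status``; needed for the
        baseline fit.
    """

    def __init__(
        self,
        cohort: Cohort,
        pool: OutcomePool,
        scenarios: Sequence[Scenario],
        m: int = 1000,
        covariate_log_hrs: Mapping[str, float] | None = None,
        frame: pd.DataFrame | None = None,
    ) -> None:
        if not scenarios:
            raise ValueError("at least one scenario is required")
        for sc in scenarios:
            if sc.confounder is None:
                raise ValueError(f"scenario {sc.name!r} lacks a confounder spec")
        if m < 1:
            raise ValueError("m must be >= 1")
        self.cohort = cohort
        self.pool = pool
        self.scenarios = list(scenarios)
        self.m = m
        self.frame = frame
        self._covariate_log_hrs = dict(covariate_log_hrs) if covariate_log_hrs else None
        self._baseline: EstimateRecord | None = None

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        scenarios: Sequence[Scenario],
        m: int = 1000,
        covariate_cols: Sequence[str] | None = None,
        **kwargs,
    ) -> "ConfounderBiasStudy":
        """Build the study from a subject table already in memory."""
        if covariate_cols is None:
            covariate_cols = [
                c for c in frame.columns if c not in ("id", "exposure", "time", "status")
            ]
        cohort = Cohort(
            ids=frame["id"].to_numpy(),
            exposure=frame["exposure"].to_numpy(dtype=int),
            covariates=frame[list(covariate_cols)].astype(float),
        )
        status = frame["status"].to_numpy(dtype=int)
        times = frame["time"].to_numpy(dtype=float)
        pool = OutcomePool(times[status == 1], times[status == 0])
        return cls(cohort, pool, scenarios, m=m, frame=frame, **kwargs)

    def baseline(self) -> EstimateRecord:
        """Step-2 uncorrected fit on the original data (exposure estimate)."""
        if self.frame is None:
            raise ValueError("baseline fit requires the original subject table")
        if self._baseline is None:
            self._baseline = fit_cox(
                self.frame, self.cohort.covariate_names, model_label="uncorrected"
            )
        return self._baseline

    @property
    def covariate_log_hrs(self) -> dict[str, float]:
        """True-model covariate effects (uncorrected fit unless user-supplied)."""
        if self._covariate_log_hrs is None:
            if self.frame is None:
                raise ValueError(
                    "supply covariate_log_hrs or the original frame to estimate them"
                )
            params = cox_coefficients(self.frame, self.cohort.covariate_names)
            self._covariate_log_hrs = {
                k: float(v) for k, v in params.items() if k != "exposure"
            }
        return self._covariate_log_hrs

    def fit(self, base_seed: int = 0) -> QBAResults:
        """Run all scenarios; returns per-repetition estimates and summaries."""
        cov_hrs = self.covariate_log_hrs
        covs = self.cohort.covariate_names
        rows: list[dict] = []
        summaries: dict[tuple[str, str], PerformanceSummary] = {}
        records: dict[tuple[str, str], list[EstimateRecord]] = {}
        for sc in self.scenarios:
            m = sc.m or self.m
            seed = base_seed if sc.base_seed is None else sc.base_seed
            for r in range(m):
                rng = _rep_rng(seed, sc.name, r)
                oracle = make_oracle_with_stage(self.cohort, sc, self.pool, rng, cov_hrs)
                imperfect = make_imperfect_confounder(oracle)
                fits = {
                    "oracle": fit_cox(oracle.frame, covs + ["stage"], model_label="oracle"),
                    "no_confounder": fit_cox(
                        imperfect.frame, covs, model_label="no_confounder"
                    ),
                }
                for label, rec in fits.items():
                    records.setdefault((sc.name, label), []).append(rec)
                    rows.append(_estimate_row(sc.name, r, rec))
            for label in ("oracle", "no_confounder"):
                recs = records[(sc.name, label)]
                _log_nonconverged(sc.name, label, recs)
                summaries[(sc.name, label)] = summarize(recs, sc.true_log_hr)
        provenance = self._provenance(base_seed)
        baseline = {"uncorrected": self.baseline()} if self.frame is not None else {}
        return QBAResults(
            estimates=pd.DataFrame(rows, columns=_EST_COLS),
            summaries=summaries,
            baseline=baseline,
            provenance=provenance,
        )

    def _provenance(self, base_seed: int) -> dict:
        cfg = {
            "study": "confounder",
            "n": self.cohort.n,
            "n_events": self.pool.n_events,
            "m": self.m,
            "base_seed": base_seed,
            "scenarios": [sc.name for sc in self.scenarios],
            "covariate_log_hrs": self.covariate_log_hrs,
        }
        return {**cfg, "config_hash": _config_hash(cfg), "version": __version__}


class IntervalCensoringStudy:
    """Quantify the impact of interval-censored event times on a TVE effect.

    Each repetition draws true event days inside the observed between-visits
    intervals, assigns them to subjects with the permutational algorithm
    (exposure looked up at the event day in the daily panel), then fits Cox
    models at the true days (oracle) and at midpoint- and endpoint-imputed
    days (imperfect).
    """

    MODELS = ("true_times", "midpoint", "endpoint")

    def __init__(
        self,
        tve_cohort: TVECohort,
        scenarios: Sequence[Scenario],
        m: int = 1000,
        covariate_log_hrs: Mapping[str, float] | None = None,
        covariate_names: Sequence[str] = ("age", "male"),
    ) -> None:
        if not scenarios:
            raise ValueError("at least one scenario is required")
        if m < 1:
            raise ValueError("m must be >= 1")
        self.cohort = tve_cohort
        self.scenarios = list(scenarios)
        self.m = m
        self.covariate_names = list(covariate_names)
        self._covariate_log_hrs = dict(covariate_log_hrs) if covariate_log_hrs else None
        self._baseline: dict[str, EstimateRecord] | None = None

    def baseline(self) -> dict[str, EstimateRecord]:
        """Step-2 uncorrected fits on the observed data, one per imputation.

        The observed interval-censored events are placed at the midpoint or at
        the endpoint of their own intervals and the time-varying Cox model is
        fitted to each version.
        """
        if self._baseline is None:
            self._baseline = {}
            observed = observed_dataset(self.cohort)
            for strategy in ("midpoint", "endpoint"):
                ds = build_imperfect_tve(observed, strategy)
                rec = fit_cox_tve(
                    ds.to_counting_process(), self.covariate_names, model_label=strategy
                )
                self._baseline[strategy] = rec
        return self._baseline

    @property
    def covariate_log_hrs(self) -> dict[str, float]:
        """True-model covariate effects; default from the midpoint baseline fit."""
        if self._covariate_log_hrs is None:
            observed = build_imperfect_tve(observed_dataset(self.cohort), "midpoint")
            params = cox_tve_coefficients(observed.to_counting_process(), self.covariate_names)
            self._covariate_log_hrs = {
                k: float(v) for k, v in params.items() if k != "exposure"
            }
        return self._covariate_log_hrs

    def fit(self, base_seed: int = 0) -> QBAResults:
        cov_hrs = self.covariate_log_hrs
        rows: list[dict] = []
        summaries: dict[tuple[str, str], PerformanceSummary] = {}
        comparisons: dict[str, ComparisonSummary] = {}
        for sc in self.scenarios:
            m = sc.m or self.m
            models = sc.strategies or self.MODELS
            seed = base_seed if sc.base_seed is None else sc.base_seed
            records: dict[str, list[EstimateRecord]] = {lab: [] for lab in models}
            for r in range(m):
                rng = _rep_rng(seed, sc.name, r)
                oracle = build_oracle_tve(self.cohort, sc, rng, cov_hrs)
                datasets = {}
                if "true_times" in models:
                    datasets["true_times"] = oracle
                for strategy in ("midpoint", "endpoint"):
                    if strategy in models:
                        datasets[strategy] = build_imperfect_tve(oracle, strategy)
                for label, ds in datasets.items():
                    rec = fit_cox_tve(
                        ds.to_counting_process(), self.covariate_names, model_label=label
                    )
                    records[label].append(rec)
                    rows.append(_estimate_row(sc.name, r, rec))
            for label, recs in records.items():
                _log_nonconverged(sc.name, label, recs)
                summaries[(sc.name, label)] = summarize(recs, sc.true_log_hr)
            if "midpoint" in records and "endpoint" in records:
                comparisons[sc.name] = compare_models(
                    records["midpoint"], records["endpoint"], sc.true_log_hr
                )
        return QBAResults(
            estimates=pd.DataFrame(rows, columns=_EST_COLS),
            summaries=summaries,
            comparisons=comparisons,
            provenance=self._provenance(base_seed),
        )

    def redistribution_analysis(self, n_reps: int = 1000, base_seed: int = 0) -> dict:
        """Sensitivity analysis redistributing observed events in their intervals.

        Each replication moves every observed event to a uniform random day in
        its own between-visits interval (keeping the subject) and refits the
        time-varying Cox model. Returns the mean and empirical SE of the
        exposure log HR plus the raw estimates.
        """
        estimates = []
        for r in range(n_reps):
            rng = _rep_rng(base_seed, "redistribution", r)
            ds = redistribute_event_times(self.cohort, rng)
            rec = fit_cox_tve(ds.to_counting_process(), self.covariate_names, model_label="redistributed")
            if rec.converged:
                estimates.append(rec.log_hr)
        est = np.asarray(estimates)
        return {
            "mean_log_hr": float(est.mean()),
            "empirical_se": float(est.std(ddof=1)),
            "n_reps": len(est),
            "estimates": est,
        }

    def _provenance(self, base_seed: int) -> dict:
        cfg = {
            "study": "interval",
            "n": self.cohort.n,
            "n_events": self.cohort.n_events,
            "m": self.m,
            "base_seed": base_seed,
            "scenarios": [sc.name for sc in self.scenarios],
            "covariate_log_hrs": self.covariate_log_hrs,
        }
        return {**cfg, "config_hash": _config_hash(cfg), "version": __version__}


def _estimate_row(scenario: str, rep: int, rec: EstimateRecord) -> dict:
    return {
        "scenario": scenario,
        "rep": rep,
        "model": rec.model_label,
        "log_hr": rec.log_hr,
        "se": rec.se,
        "ci_low": rec.ci_low,
        "ci_high": rec.ci_high,
        "converged": rec.converged,
        "n_events": rec.n_events,
    }


def _log_nonconverged(scenario: str, label: str, recs: Sequence[EstimateRecord]) -> None:
    bad = sum(not r.converged for r in recs)
    if bad:
        logger.warning("%s/%s: %d of %d fits did not converge", scenario, label, bad, len(recs))


def table1_scenarios(m: int | None = None) -> list[Scenario]:
    """The eight confounder scenarios of the motivating prognostic study:
    true exposure HR in {1.0, 1.3, 1.5, 2.0}, stage-exposure OR in
    {1.0, 1.2, 2.0}, stage-mortality HR in {1.0, 4.0}."""
    grid = [
        ("s1", 1.0, 1.2, 4.0),
        ("s2", 1.3, 1.2, 4.0),
        ("s3", 1.5, 1.2, 4.0),
        ("s4", 2.0, 1.2, 4.0),
        ("s5", 1.3, 1.0, 4.0),
        ("s6", 1.0, 2.0, 4.0),
        ("s7", 1.3, 2.0, 4.0),
        ("s8", 1.3, 1.0, 1.0),
    ]
    return [
        Scenario(
            name=name,
            true_hr_exposure=hr_x,
            confounder=ConfounderSpec(or_exposure=or_xs, hr_outcome=hr_s),
            m=m,
        )
        for name, hr_x, or_xs, hr_s in grid
    ]


def table2_scenarios(m: int | None = None) -> list[Scenario]:
    """The four TVE scenarios: true exposure HR in {1.0, 1.5, 2.0, 2.5}."""
    return [
        Scenario(name=f"hr{hr:g}", true_hr_exposure=hr, strategies=IntervalCensoringStudy.MODELS, m=m)
        for hr in (1.0, 1.5, 2.0, 2.5)
    ]
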