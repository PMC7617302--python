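"""Simulation of an unmeasured binary confounder (Example-1-style studies).

A binary prognostic factor — cancer stage III/IV vs I/II in the motivating
colon-cancer analysis — is simulated from a multivariable logistic model on the
observed exposure and covariates, included in the true hazard model used by the
permutational algorithm, and then deleted to create the imperfect dataset. The
contrast between Cox fits with and without the simulated factor separates
confounding bias from the noncollapsibility shift of hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, ConfounderSpec, OutcomePool, Scenario, SurvivalDataset, TrueHazardModel
from .permutation import generate_oracle

__all__ = [
    "StageModel",
    "calibrate_intercept",
    "simulate_stage",
    "make_oracle_with_stage",
    "make_imperfect_confounder",
]


@dataclass(frozen=True)
class StageModel:
    """Logistic model generating the binary confounder.

    ``P(S_i = 1) = expit(alpha + log(OR_x) * x_i + sum_c log(OR_c) * c_i)``
    with the intercept ``alpha`` calibrated so that the cohort-average
    probability (the marginal prevalence) hits ``target_prevalence``.
    """

    log_or_exposure: float
    covariate_log_ors: Mapping[str, float] = field(default_factory=dict)
    target_prevalence: float = 0.35
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target prevalence must be in (0, 1)")
        vals = [self.log_or_exposure, *self.covariate_log_ors.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("log odds ratios must be finite")

    @classmethod
    def from_spec(cls, spec: ConfounderSpec) -> "StageModel":
        return cls(
            log_or_exposure=float(np.log(spec.or_exposure)),
            covariate_log_ors={k: float(np.log(v)) for k, v in spec.or_covariates.items()},
            target_prevalence=spec.target_prevalence,
        )


def _linear_part(model: StageModel, cohort: Cohort) -> np.ndarray:
    eta = model.log_or_exposure * np.asarray(cohort.exposure, dtype=float)
    for name, b in model.covariate_log_ors.items():
        if name not in cohort.covariates.columns:
            raise KeyError(f"unknown covariate {name!r} in stage model")
        eta += b * cohort.covariates[name].to_numpy(dtype=float)
    return eta


def calibrate_intercept(model: StageModel, cohort: Cohort, tol: float = 1e-10) -> float:
    """Intercept making the cohort-mean probability equal the target prevalence.

    ``mean_i expit(alpha + eta_i)`` is strictly increasing in ``alpha``, so the
    root is found by bracketed root-finding to within ``1e-6`` of the target
    (far tighter in practice).
    """
    eta = _linear_part(model, cohort)
    target = model.target_prevalence

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)) - target)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError("intercept calibration failed to bracket the target")
    return float(brentq(gap, lo, hi, xtol=tol))


def simulate_stage(
    cohort: Cohort, model: StageModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the binary confounder ``S_i ~ Bernoulli(p_i)`` for each subject.

    Returns ``(S, p)``; the per-subject probabilities are exposed for testing.
    The intercept is calibrated on the fly when the model does not carry one.
    """
    alpha = model.intercept
    if alpha is None:
        alpha = calibrate_intercept(model, cohort)
    p = expit(alpha + _linear_part(model, cohort))
    s = (rng.random(cohort.n) < p).astype(int)
    return s, p


def make_oracle_with_stage(
    cohort: Cohort,
    scenario: Scenario,
    pool: OutcomePool,
    rng: np.random.Generator,
    covariate_log_hrs: Mapping[str, float] | None = None,
) -> SurvivalDataset:
    """One oracle dataset: simulated stage plus permuted outcomes.

    The stage indicator is drawn first, then every pooled outcome is assigned
    by the permutational algorithm under the true model combining the
    scenario's exposure and stage hazard ratios with the supplied covariate
    log hazard ratios (typically the uncorrected fit on the source data).
    """
    if scenario.confounder is None:
        raise ValueError("scenario has no confounder specification")
    spec = scenario.confounder
    stage_model = StageModel.from_spec(spec)
    s, _ = simulate_stage(cohort, stage_model, rng)

    true_model = TrueHazardModel(
        log_hr_exposure=scenario.true_log_hr,
        covariate_log_hrs=dict(covariate_log_hrs or {}),
        log_hr_confounder=float(np.log(spec.hr_outcome)),
        confounder_name="stage",
    )
    extended = cohort.with_covariate("stage", s)
    return generate_oracle(extended, true_model, pool, rng, mode="permute_all")


def make_imperfect_confounder(oracle: SurvivalDataset) -> SurvivalDataset:
    """The imperfect dataset: the oracle with the simulated confounder deleted.

    Exposure, measured covariates and the assigned outcomes are untouched.
    """
    if "stage" not in oracle.frame.columns:
        raise ValueError("oracle dataset carries no stage column")
    return SurvivalDataset(frame=oracle.frame.drop(columns=["stage"]))


# convenience: closed-form intercept when no covariate is associated
def null_model_intercept(target_prevalence: float) -> float:
    """logit of the target — the calibrated intercept when all ORs are 1."""
    return float(logit(target_prevalence))
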