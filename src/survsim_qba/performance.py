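"""Monte-Carlo performance measures and replication-count planning.

Implements the standard simulation-study summaries — bias, relative bias,
empirical SE, RMSE, CI coverage, type-I error / power — together with their
Monte-Carlo standard errors, a paired model-comparison summary, and the normal
approximation used to choose the number of repetitions so that a bias of a
given size (expressed as a fraction of the empirical SE) is detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .estimation import EstimateRecord, Z_975

__all__ = [
    "PerformanceSummary",
    "ComparisonSummary",
    "summarize",
    "compare_models",
    "power_for_bias_detection",
    "required_repetitions",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Per-scenario Monte-Carlo summary of one analysis model.

    ``rejection_rate`` is the fraction of repetitions whose 95% CI excludes 0:
    the empirical type-I error when the true log HR is 0, the empirical power
    otherwise. ``rmse**2 == bias**2 + empirical_se**2`` exactly (both use the
    n-1 variance).
    """

    true_log_hr: float
    m_used: int
    bias: float
    bias_mcse: float
    relative_bias_pct: float | None
    empirical_se: float
    rmse: float
    coverage: float
    coverage_mcse: float
    rejection_rate: float
    rejection_mcse: float

    def bias_ci_excludes_zero(self) -> bool:
        """Whether the 95% CI for the bias itself excludes 0."""
        return abs(self.bias) > Z_975 * self.bias_mcse

    def to_dict(self) -> dict:
        return {
            "true_log_hr": self.true_log_hr,
            "m_used": self.m_used,
            "bias": self.bias,
            "bias_mcse": self.bias_mcse,
            "relative_bias_pct": self.relative_bias_pct,
            "empirical_se": self.empirical_se,
            "rmse": self.rmse,
            "coverage": self.coverage,
            "coverage_mcse": self.coverage_mcse,
            "rejection_rate": self.rejection_rate,
            "rejection_mcse": self.rejection_mcse,
        }


@dataclass(frozen=True)
class ComparisonSummary:
    """Paired comparison of two analysis models over the same repetitions."""

    bias_ratio: float | None
    rmse_ratio: float | None
    pct_closer: float

    def to_dict(self) -> dict:
        return {
            "bias_ratio": self.bias_ratio,
            "rmse_ratio": self.rmse_ratio,
            "pct_closer": self.pct_closer,
        }


def _estimates(records: Sequence[EstimateRecord]) -> list[EstimateRecord]:
    return [r for r in records if r.converged]


def summarize(records: Sequence[EstimateRecord], true_log_hr: float) -> PerformanceSummary:
    """Monte-Carlo performance measures of a sequence of fitted estimates.

    bias = mean estimate - truth; relative bias = 100 * bias / truth (not
    applicable at truth 0); empirical SE = sample SD (n-1 denominator);
    RMSE = sqrt(bias^2 + Var); coverage = fraction of 95% CIs containing the
    truth; rejection = fraction excluding 0. MCSEs: empirical_se/sqrt(m) for
    bias, binomial sqrt(p(1-p)/m) for the proportions.
    """
    recs = _estimates(records)
    m = len(recs)
    if m < 2:
        raise ValueError("need at least 2 converged estimates")
    est = np.array([r.log_hr for r in recs])
    bias = float(est.mean() - true_log_hr)
    var = float(est.var(ddof=1))
    emp_se = math.sqrt(var)
    rmse = math.sqrt(bias**2 + var)
    coverage = float(np.mean([r.covers(true_log_hr) for r in recs]))
    rejection = float(np.mean([r.rejects_null() for r in recs]))
    rel = None if true_log_hr == 0 else 100.0 * bias / true_log_hr
    return PerformanceSummary(
        true_log_hr=true_log_hr,
        m_used=m,
        bias=bias,
        bias_mcse=emp_se / math.sqrt(m),
        relative_bias_pct=rel,
        empirical_se=emp_se,
        rmse=rmse,
        coverage=coverage,
        coverage_mcse=math.sqrt(coverage * (1 - coverage) / m),
        rejection_rate=rejection,
        rejection_mcse=math.sqrt(rejection * (1 - rejection) / m),
    )


def compare_models(
    estimates_a: Sequence[EstimateRecord],
    estimates_b: Sequence[EstimateRecord],
    true_log_hr: float,
) -> ComparisonSummary:
    """Paired comparison: bias and RMSE ratios (b over a) and the percentage of
    repetitions where model a's estimate is strictly closer to the truth.

    Requires the two sequences to come from the same repetitions (same seeds)
    in the same order; ties count as "not closer". A zero bias for model a
    makes the bias ratio undefined (reported as None).
    """
    if len(estimates_a) != len(estimates_b):
        raise ValueError("paired comparison requires equal-length estimate sequences")
    pairs = [
        (ra, rb)
        for ra, rb in zip(estimates_a, estimates_b)
        if ra.converged and rb.converged
    ]
    a = [ra for ra, _ in pairs]
    b = [rb for _, rb in pairs]
    sa = summarize(a, true_log_hr)
    sb = summarize(b, true_log_hr)
    bias_ratio = None if sa.bias == 0 else sb.bias / sa.bias
    rmse_ratio = None if sa.rmse == 0 else sb.rmse / sa.rmse
    ea = np.array([r.log_hr for r in a])
    eb = np.array([r.log_hr for r in b])
    closer = np.abs(ea - true_log_hr) < np.abs(eb - true_log_hr)
    return ComparisonSummary(
        bias_ratio=bias_ratio,
        rmse_ratio=rmse_ratio,
        pct_closer=100.0 * float(closer.mean()),
    )


def power_for_bias_detection(m: int, bias_as_fraction_of_se: float) -> float:
    """Probability that the 95% CI for bias excludes 0 under a normal model.

    With m repetitions and a true bias equal to ``f`` empirical SEs, the
    standardized bias estimate is Normal(f*sqrt(m), 1), so the two-sided Wald
    test rejects with probability
    ``Phi(f*sqrt(m) - z_.975) + Phi(-f*sqrt(m) - z_.975)``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    shift = bias_as_fraction_of_se * math.sqrt(m)
    return float(norm.cdf(shift - Z_975) + norm.cdf(-shift - Z_975))


def required_repetitions(target_power: float, bias_as_fraction_of_se: float) -> int:
    """Smallest number of repetitions reaching the target detection power."""
    if not 0.05 < target_power < 1:
        raise ValueError("target power must be in (0.05, 1)")
    if bias_as_fraction_of_se <= 0:
        raise ValueError("bias fraction must be > 0")
    # one-sided closed form as a starting guess, then search for the minimum
    guess = ((Z_975 + norm.ppf(target_power)) / bias_as_fraction_of_se) ** 2
    m = max(1, int(math.floor(guess)) - 2)
    while power_for_bias_detection(m, bias_as_fraction_of_se) < target_power:
        m += 1
    while m > 1 and power_for_bias_detection(m - 1, bias_as_fraction_of_se) >= target_power:
        m -= 1
    return m
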