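"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: assignment
probabilities come from explicit enumeration of the sequential weighted
sampling process, and Cox coefficients from a hand-written partial likelihood
maximized with scipy.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize_scalar


def enumerate_assignment_probs(
    weights: np.ndarray,
    event_times: np.ndarray,
    admissible_until: np.ndarray | None = None,
) -> dict[tuple[int, ...], float]:
    """Exact probability of every ordered event-to-subject assignment.

    Events are taken in ascending time order (times assumed distinct). At each
    event time t the probability of picking subject i is w_i / sum_j w_j over
    subjects not yet assigned (and with admissible_until[j] >= t if given).
    """
    w = np.asarray(weights, dtype=float)
    times = np.sort(np.asarray(event_times, dtype=float))
    n = len(w)
    out: dict[tuple[int, ...], float] = {}
    for seq in permutations(range(n), len(times)):
        p = 1.0
        taken: set[int] = set()
        for t, s in zip(times, seq):
            elig = [
                j
                for j in range(n)
                if j not in taken
                and (admissible_until is None or admissible_until[j] >= t)
            ]
            if s not in elig:
                p = 0.0
                break
            p *= w[s] / w[list(elig)].sum()
            taken.add(s)
        if p > 0:
            out[seq] = p
    return out


def cox_loglik_no_ties(beta: float, x: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    """Cox partial log-likelihood for a single covariate, distinct event times."""
    ll = 0.0
    for t in time[status == 1]:
        i = int(np.flatnonzero((time == t) & (status == 1))[0])
        risk = time >= t
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_mle_no_ties(x: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    """Maximize the hand-written partial likelihood by bounded scalar search."""
    res = minimize_scalar(
        lambda b: -cox_loglik_no_ties(b, x, time, status),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
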