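"""Specialized Cox partial-likelihood solver for a single binary covariate.

The marginalization procedure ends with a Cox fit of heavily tied simulated
data on the simulated exposure alone, and the unadjusted comparator is the
same model on the original data.  With one binary covariate the Efron partial
likelihood depends on the data only through per-event-time counts (events and
risk-set sizes by arm), so it can be grouped and maximized by a scalar Newton
iteration -- orders of magnitude faster than a general solver on the expanded
records, and exactly equal to it (this equality is asserted in the test
suite against lifelines).

Efron's tie handling: for an event time with d events of which d1 are in the
exposed arm, risk sums S = n0 + n1*e^b and S_d = d0 + d1*e^b contribute

    sum_{r=0}^{d-1} log(S - (r/d) * S_d)

to the negative log partial likelihood, minus b*d1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fast_binary_cox"]


def fast_binary_cox(
    time: np.ndarray,
    event: np.ndarray,
    exposure: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> float:
    """Maximum Efron partial-likelihood coefficient of a binary covariate.

    Raises ValueError when the likelihood is monotone (all events in one arm
    at every event time with mixed risk sets cannot happen; the practical
    trigger is an arm with no events at all while the other has some).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    x = np.asarray(exposure)
    if e.sum() < 1:
        raise ValueError("no events; Cox fit is not possible")

    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    n = len(t)

    ev_mask = e == 1
    uniq, first_idx = np.unique(t[ev_mask], return_index=True)
    # counts of events by arm at each unique event time
    grp = np.searchsorted(uniq, t[ev_mask])
    d1 = np.bincount(grp, weights=x[ev_mask].astype(float), minlength=len(uniq))
    d = np.bincount(grp, minlength=len(uniq)).astype(float)
    d0 = d - d1
    # risk-set sizes by arm: subjects with t_i >= t_k
    start = np.searchsorted(t, uniq, side="left")
    cum_x = np.concatenate(([0.0], np.cumsum(x)))
    n_total = (n - start).astype(float)
    n1 = cum_x[n] - cum_x[start]
    n0 = n_total - n1

    if d1.sum() == 0 or d0.sum() == 0:
        raise ValueError(
            "all events fall in a single exposure arm; the partial likelihood "
            "is monotone and the coefficient diverges"
        )

    # expand per-event Efron fractions r/d for each tie group
    reps = d.astype(int)
    frac = (np.arange(int(d.sum())) - np.repeat(np.concatenate(([0], np.cumsum(reps)[:-1])), reps)) / np.repeat(d, reps)
    g = np.repeat(np.arange(len(uniq)), reps)  # group index per Efron term
    n0g, n1g = n0[g], n1[g]
    d0g, d1g = d0[g], d1[g]
    sum_d1 = d1.sum()

    beta = 0.0
    for _ in range(max_iter):
        a = np.exp(beta)
        denom = (n0g + n1g * a) - frac * (d0g + d1g * a)
        num1 = a * (n1g - frac * d1g)  # d(denom)/d(beta)
        score = sum_d1 - (num1 / denom).sum()
        # -d(score)/d(beta): num1' = num1, so each term is num1*(denom-num1)/denom^2
        info = (num1 * (denom - num1) / (denom * denom)).sum()
        if info <= 0:
            raise ValueError("partial likelihood is degenerate (zero information)")
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(score) < tol and abs(step) < 1e-12:
            break
    else:
        if abs(score) > 1e-6:
            raise ValueError(
                f"Newton iteration did not converge (score {score:.2e}); "
                "possible monotone likelihood"
            )
    return float(beta)
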