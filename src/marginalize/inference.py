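"""Nonparametric bootstrap standard errors and percentile confidence intervals.

Subjects (rows) are resampled with replacement and the *entire* estimation
procedure is re-run on each resample -- for the simulation-based hazard-ratio
estimator this includes re-fitting both conditional Cox models and redoing
the internal simulation with a fresh substream.  Failed replicates (e.g.
separation in a resample) are dropped and counted, never silently absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

__all__ = ["BootstrapResult", "bootstrap"]


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate estimates with their sd (the bootstrap SE) and the
    2.5th/97.5th percentile confidence interval."""

    replicate_estimates: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    n_failed: int

    @property
    def n_success(self) -> int:
        return len(self.replicate_estimates)


def _one_replicate(estimator, data, n, seed_pair, stratify_by):
    rng = np.random.default_rng(seed_pair[0])
    if stratify_by is None:
        idx = rng.integers(0, n, size=n)
    else:
        idx = np.concatenate(
            [rng.choice(g, size=len(g), replace=True) for g in stratify_by]
        )
    try:
        return float(estimator(data.subset(idx), int(seed_pair[1])))
    except Exception:
        return np.nan


def bootstrap(
    estimator: Callable,
    data,
    B: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    stratify_by_exposure: bool = False,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Nonparametric bootstrap of ``estimator`` over row resamples of ``data``.

    Parameters
    ----------
    estimator : callable ``(data, seed) -> float``
        Re-run in full on each resample; the per-replicate ``seed`` drives any
        internal simulation and is derived deterministically from ``seed``, so
        parallel execution is order-independent.
    data : BinaryDataset or SurvivalDataset (anything with .n and .subset).
    stratify_by_exposure : resample within exposure arms instead of pooled.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    n = data.n
    strata = None
    if stratify_by_exposure:
        strata = [np.flatnonzero(data.exposure == v) for v in (0, 1)]
    # counter-based per-replicate seeds: independent of execution order
    children = np.random.SeedSequence(seed).spawn(B)
    seed_pairs = [c.generate_state(2) % (2**31) for c in children]
    if n_jobs == 1:
        reps = [_one_replicate(estimator, data, n, sp, strata) for sp in seed_pairs]
    else:
        reps = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(estimator, data, n, sp, strata)
            for sp in seed_pairs
        )
    reps = np.asarray(reps, dtype=float)
    ok = reps[np.isfinite(reps)]
    n_failed = B - len(ok)
    if len(ok) == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if n_failed > 0.05 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed and were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        replicate_estimates=ok,
        se=float(np.std(ok, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_failed=n_failed,
    )
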