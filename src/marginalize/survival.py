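"""Conditional model fitting and covariate-standardized curves.

Logistic and Cox proportional-hazards fits are delegated to statsmodels and
lifelines respectively (Efron tie handling by default).  On top of the Cox
coefficients this module computes the Breslow nonparametric estimator of the
cumulative baseline hazard and the standardized (g-computation) survival
curve

    S_hat_x(t) = (1/n) * sum_i exp( -H0_hat(t) * exp(lam_hat*x + rho_hat'C_i) ),

the average of each subject's model-implied survival curve under exposure
``x`` over the empirical covariate distribution, optionally reweighted to a
different covariate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.special import expit

from .datasets import BinaryDataset, SurvivalDataset

__all__ = [
    "StepCurve",
    "ModelFit",
    "fit_logistic",
    "fit_cox",
    "intercept_only_cox",
    "breslow_baseline",
    "standardized_survival",
    "normalize_weights",
]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous piecewise-constant function on [0, inf).

    ``times`` are the (strictly increasing) jump locations, ``values`` the
    function values from each jump onward, and ``value_before_first`` the
    value on [0, times[0]).
    """

    times: np.ndarray
    values: np.ndarray
    value_before_first: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
            raise ValueError("times must be positive and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right")
        out = np.where(
            idx == 0,
            self.value_before_first,
            self.values[np.maximum(idx - 1, 0)],
        )
        return out if np.ndim(t) else float(out)

    def truncated(self, tmax: float) -> "StepCurve":
        keep = self.times <= tmax
        return StepCurve(self.times[keep], self.values[keep], self.value_before_first)


@dataclass(frozen=True)
class ModelFit:
    """A fitted conditional model: exposure coefficient, covariate
    coefficients, and (Cox only) the Breslow baseline cumulative hazard."""

    kind: str  # 'logistic' or 'cox'
    exposure_coef: float
    covariate_coefs: np.ndarray
    intercept: float | None = None
    baseline_cumhaz: StepCurve | None = None
    n_subjects: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "covariate_coefs", np.atleast_1d(np.asarray(self.covariate_coefs, dtype=float))
        )
        if self.kind == "cox" and self.intercept is not None:
            raise ValueError("cox fits have no intercept")
        if self.kind == "logistic" and self.intercept is None:
            raise ValueError("logistic fits must carry an intercept")

    def linear_predictor(self, exposure, covariates, x: int | None = None) -> np.ndarray:
        """Covariate part of the linear predictor (no intercept); ``x``
        overrides the observed exposure when standardizing."""
        xv = np.full(len(covariates), float(x)) if x is not None else np.asarray(exposure, float)
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        # unadjusted fits carry no covariate coefficients; ignore extra columns
        c = c[:, : self.covariate_coefs.size]
        return self.exposure_coef * xv + c @ self.covariate_coefs

    def predicted_risk(self, covariates, x: int) -> np.ndarray:
        """Logistic fits: expit(mu + nu*x + gamma'C_i)."""
        if self.kind != "logistic":
            raise ValueError("predicted_risk is defined for logistic fits")
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        return expit(self.intercept + self.exposure_coef * x + c @ self.covariate_coefs)


def normalize_weights(weights, n: int) -> np.ndarray:
    """Validate a nonnegative weight vector and normalize it to mean 1."""
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    return w * (n / total)


def _design(data, adjust: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.asarray(data.exposure, dtype=float)]
    names = ["exposure"]
    if adjust:
        for j in range(data.n_covariates):
            cols.append(data.covariates[:, j])
            names.append(f"c{j + 1}")
    return np.column_stack(cols), names


def fit_logistic(
    data: BinaryDataset, adjust: bool = True, weights=None
) -> ModelFit:
    """Maximum-likelihood logistic regression of the outcome on exposure
    (and, if ``adjust``, the covariates).

    Raises on a single-class outcome, a constant exposure, or (quasi-)perfect
    separation, naming the offending column.
    """
    y = data.outcome
    if y.min() == y.max():
        raise ValueError("outcome takes a single value; logistic fit is degenerate")
    if data.exposure.min() == data.exposure.max():
        raise ValueError("exposure is constant; its coefficient is not identified")
    design, names = _design(data, adjust)
    exog = sm.add_constant(design, prepend=True)
    w = normalize_weights(weights, data.n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w).fit(
                maxiter=200
            )
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise ValueError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        worst = names[int(np.abs(params[1:]).argmax())]
        raise ValueError(
            f"logistic fit appears separated (runaway coefficient on {worst!r})"
        )
    return ModelFit(
        kind="logistic",
        intercept=float(params[0]),
        exposure_coef=float(params[1]),
        covariate_coefs=params[2:] if adjust else np.empty(0),
        n_subjects=data.n,
        n_events=int(y.sum()),
    )


def fit_cox(
    data: SurvivalDataset,
    adjust: bool = True,
    ties: str = "efron",
    weights=None,
    with_baseline: bool = True,
    engine: str = "auto",
) -> ModelFit:
    """Maximum partial-likelihood Cox fit, with the Breslow cumulative
    baseline hazard attached.

    ``ties`` is 'efron' (default) or 'breslow'.  General fits go through
    lifelines; the exposure-only unweighted Efron model is solved by the
    grouped scalar Newton iteration in :mod:`marginalize._fastcox` (equal to
    lifelines to solver tolerance; asserted in the tests).  ``engine`` can
    force ``'lifelines'``.
    """
    if data.n_events < 1:
        raise ValueError("no events in the data; Cox fit is not possible")
    if data.exposure.min() == data.exposure.max():
        raise ValueError("exposure is constant; its coefficient is not identified")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if engine not in ("auto", "lifelines"):
        raise ValueError("engine must be 'auto' or 'lifelines'")
    exposure_only = (not adjust) or data.n_covariates == 0
    if (
        engine == "auto"
        and exposure_only
        and weights is None
        and ties == "efron"
    ):
        from ._fastcox import fast_binary_cox

        try:
            beta = fast_binary_cox(data.time, data.event, data.exposure)
        except ValueError as exc:
            raise ValueError(f"Cox fit failed: {exc}") from exc
        fit = ModelFit(
            kind="cox",
            exposure_coef=beta,
            covariate_coefs=np.empty(0),
            n_subjects=data.n,
            n_events=data.n_events,
        )
        if with_baseline:
            curve = breslow_baseline(fit, data, adjust=False)
            fit = ModelFit(
                kind="cox", exposure_coef=beta, covariate_coefs=np.empty(0),
                baseline_cumhaz=curve, n_subjects=data.n, n_events=data.n_events,
            )
        return fit
    design, names = _design(data, adjust)
    df = pd.DataFrame(design, columns=names)
    df["time"] = data.time
    df["event"] = data.event
    kwargs = {}
    if weights is not None:
        df["_w"] = normalize_weights(weights, data.n)
        kwargs = {"weights_col": "_w", "robust": True}
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", **kwargs)
    except ConvergenceError as exc:
        raise ValueError(
            "Cox partial likelihood did not converge (possibly monotone "
            f"likelihood / complete separation): {exc}"
        ) from exc
    params = cph.params_.reindex(names).to_numpy()
    fit = ModelFit(
        kind="cox",
        exposure_coef=float(params[0]),
        covariate_coefs=params[1:] if adjust else np.empty(0),
        n_subjects=data.n,
        n_events=data.n_events,
    )
    if with_baseline:
        curve = breslow_baseline(fit, data, weights=weights, adjust=adjust)
        fit = ModelFit(
            kind="cox",
            exposure_coef=fit.exposure_coef,
            covariate_coefs=fit.covariate_coefs,
            baseline_cumhaz=curve,
            n_subjects=fit.n_subjects,
            n_events=fit.n_events,
        )
    return fit


def intercept_only_cox(data: SurvivalDataset) -> ModelFit:
    """A null Cox model: all coefficients zero, so the Breslow baseline is the
    Nelson-Aalen estimator of the pooled sample."""
    fit = ModelFit(
        kind="cox",
        exposure_coef=0.0,
        covariate_coefs=np.empty(0),
        n_subjects=data.n,
        n_events=data.n_events,
    )
    curve = breslow_baseline(fit, data)
    return ModelFit(
        kind="cox",
        exposure_coef=0.0,
        covariate_coefs=np.empty(0),
        baseline_cumhaz=curve,
        n_subjects=data.n,
        n_events=data.n_events,
    )


def breslow_baseline(
    fit: ModelFit, data: SurvivalDataset, weights=None, adjust: bool = True
) -> StepCurve:
    """Breslow estimator of the cumulative baseline hazard.

    Jumps d_k / sum_{i in risk set at t_k} w_i exp(lp_i) at each distinct
    event time t_k; zero before the first event, nondecreasing.
    """
    if fit.kind != "cox":
        raise ValueError("breslow_baseline requires a cox fit")
    w = normalize_weights(weights, data.n)
    if adjust and fit.covariate_coefs.size:
        lp = fit.linear_predictor(data.exposure, data.covariates)
    else:
        lp = fit.exposure_coef * data.exposure.astype(float)
    order = np.argsort(data.time, kind="stable")
    t_sorted = data.time[order]
    risk_sorted = (w * np.exp(lp))[order]
    suffix = np.cumsum(risk_sorted[::-1])[::-1]  # sum over {j : t_j >= t_sorted[i]}
    ev_times = data.time[data.event == 1]
    ev_w = w[data.event == 1]
    uniq, inv = np.unique(ev_times, return_inverse=True)
    d = np.bincount(inv, weights=ev_w, minlength=len(uniq))
    denom_idx = np.searchsorted(t_sorted, uniq, side="left")
    jumps = d / suffix[denom_idx]
    return StepCurve(uniq, np.cumsum(jumps), value_before_first=0.0)


def standardized_survival(
    fit: ModelFit,
    data: SurvivalDataset,
    x: int,
    weights=None,
    times: np.ndarray | None = None,
) -> StepCurve:
    """Covariate-averaged survival curve under assignment to exposure ``x``.

    Averages exp(-H0_hat(t) * exp(lam_hat*x + rho_hat'C_i)) over the subjects'
    covariate values, with optional nonnegative ``weights`` replacing the
    empirical covariate distribution (e.g. to marginalize over a reference
    population).  Returns a right-continuous step curve starting at 1.
    """
    if fit.kind != "cox" or fit.baseline_cumhaz is None:
        raise ValueError("standardized_survival requires a cox fit with a baseline")
    if x not in (0, 1):
        raise ValueError("x must be 0 or 1")
    w = normalize_weights(weights, data.n)
    if times is None:
        times = fit.baseline_cumhaz.times
        h0 = fit.baseline_cumhaz.values
    else:
        times = np.asarray(times, dtype=float)
        h0 = np.asarray(fit.baseline_cumhaz(times))
    lp = fit.linear_predictor(data.exposure, data.covariates, x=x)
    # (k, n) matrix of subject-specific survival at each grid time
    surv = np.exp(-np.outer(h0, np.exp(lp)))
    values = surv @ (w / w.sum())
    return StepCurve(times, values, value_before_first=1.0)
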