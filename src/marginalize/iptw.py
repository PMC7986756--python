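"""Inverse-probability-of-treatment-weighted (IPTW) comparators.

A logistic propensity model for exposure given the covariates yields weights
1/p_hat for the exposed and 1/(1-p_hat) for the unexposed (unstabilized by
default).  The weighted, otherwise unadjusted, logistic or Cox fit estimates
the marginal causal log OR / log HR by emulating a randomized population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datasets import BinaryDataset, SurvivalDataset
from .results import Estimate
from .survival import fit_cox, fit_logistic

__all__ = ["PropensityFit", "fit_propensity", "iptw_log_or", "iptw_log_hr"]


@dataclass(frozen=True)
class PropensityFit:
    """Logistic exposure model: coefficients (intercept first), fitted
    treatment probabilities and the implied inverse-probability weights."""

    coefficients: np.ndarray
    fitted_probabilities: np.ndarray
    weights: np.ndarray


def fit_propensity(
    covariates: np.ndarray, exposure: np.ndarray, stabilized: bool = False
) -> PropensityFit:
    """Fit the treatment model and return per-subject IPT weights.

    ``stabilized`` multiplies each arm's weights by its marginal exposure
    probability (variance reduction; identical point estimates in saturated
    settings)."""
    x = np.asarray(exposure)
    if x.min() == x.max():
        raise ValueError("exposure takes a single value; propensity fit is degenerate")
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    exog = sm.add_constant(c, prepend=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(x, exog).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ValueError(f"propensity fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        raise ValueError("propensity model appears separated")
    p = np.asarray(res.predict(exog))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    w = np.where(x == 1, 1.0 / p, 1.0 / (1.0 - p))
    if stabilized:
        w *= np.where(x == 1, x.mean(), 1.0 - x.mean())
    return PropensityFit(coefficients=params, fitted_probabilities=p, weights=w)


def _check_weights(w: np.ndarray, cap: float | None) -> None:
    if cap is not None:
        frac = w / w.sum()
        n_extreme = int((frac > cap).sum())
        if n_extreme:
            warnings.warn(
                f"{n_extreme} subject(s) carry a normalized IPT weight above "
                f"{cap:g}; estimates may be unstable",
                RuntimeWarning,
                stacklevel=3,
            )


def iptw_log_or(
    data: BinaryDataset,
    stabilized: bool = False,
    weight_cap: float | None = 0.05,
) -> Estimate:
    """IPT-weighted unadjusted logistic estimator of the marginal log OR."""
    prop = fit_propensity(data.covariates, data.exposure, stabilized)
    _check_weights(prop.weights, weight_cap)
    fit = fit_logistic(data, adjust=False, weights=prop.weights)
    return Estimate(
        estimand="log_or_marginal",
        estimate=fit.exposure_coef,
        method="iptw",
        meta={"max_weight": float(prop.weights.max()), "n": data.n},
    )


def iptw_log_hr(
    data: SurvivalDataset,
    stabilized: bool = False,
    weight_cap: float | None = 0.05,
    ties: str = "efron",
) -> Estimate:
    """IPT-weighted unadjusted Cox estimator of the marginal log HR."""
    prop = fit_propensity(data.covariates, data.exposure, stabilized)
    _check_weights(prop.weights, weight_cap)
    fit = fit_cox(data, adjust=False, ties=ties, weights=prop.weights, with_baseline=False)
    return Estimate(
        estimand="log_hr_marginal",
        estimate=fit.exposure_coef,
        method="iptw",
        meta={"max_weight": float(prop.weights.max()), "n": data.n},
    )
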