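"""Standardization (g-computation) estimator of the marginal causal log odds ratio.

After an adjusted logistic fit of the outcome on exposure and covariates, the
covariate-standardized risk under assignment to exposure x is

    Pr_hat(Y_x = 1) = (1/n) * sum_i expit(mu_hat + nu_hat*x + gamma_hat'C_i),

using the empirical distribution of the covariates as a nonparametric
estimator of their law (optionally reweighted).  The marginal log odds ratio
estimator is the log-odds contrast of the standardized risks at x=1 and x=0.
This is a covariate-*adjusted* estimator of the *marginal* causal log odds
ratio: adjusted and conditional are not synonyms.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logit

from .datasets import BinaryDataset
from .results import Estimate
from .survival import ModelFit, fit_logistic, normalize_weights

__all__ = ["standardized_risk", "marginal_log_or"]


def standardized_risk(
    fit: ModelFit, data: BinaryDataset, x: int, weights=None
) -> float:
    """Covariate-standardized risk under assignment to exposure ``x``."""
    if fit.kind != "logistic":
        raise ValueError("standardized_risk requires a logistic fit")
    if x not in (0, 1):
        raise ValueError("x must be 0 or 1")
    w = normalize_weights(weights, data.n)
    risks = fit.predicted_risk(data.covariates[:, : fit.covariate_coefs.size], x)
    return float(np.average(np.atleast_1d(risks), weights=w))


def marginal_log_or(
    fit: ModelFit | None = None,
    data: BinaryDataset | None = None,
    weights=None,
) -> Estimate:
    """Covariate-adjusted estimator of the marginal causal log odds ratio.

    ``fit`` defaults to an adjusted logistic fit of ``data``.  Raises if a
    standardized risk is degenerate (exactly 0 or 1), since the log odds are
    then infinite; such bootstrap replicates should be dropped and counted,
    not clipped.
    """
    if data is None:
        raise ValueError("data is required")
    if fit is None:
        fit = fit_logistic(data, adjust=True)
    p1 = standardized_risk(fit, data, 1, weights)
    p0 = standardized_risk(fit, data, 0, weights)
    for p in (p0, p1):
        if p <= 0.0 or p >= 1.0:
            raise ValueError(f"standardized risk {p} is degenerate; log odds undefined")
    return Estimate(
        estimand="log_or_marginal",
        estimate=float(logit(p1) - logit(p0)),
        method="adjusted_marginal",
        meta={"risk1": p1, "risk0": p0, "n": data.n},
    )
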