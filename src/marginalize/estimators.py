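"""Scikit-learn style estimators of marginal and conditional effect measures.

Every class follows the sklearn contract -- ``fit(X, y)``, ``get_params`` /
``set_params``, fitted attributes with trailing underscores -- so the
estimators compose with sklearn model selection and pipelines.  ``X`` holds
the binary exposure column (``exposure_col``, default the first column) plus
the covariates; ``y`` is the binary outcome for the odds-ratio family, and for
the hazard-ratio family either a structured array with ``event``/``time``
fields (scikit-survival convention) or a two-column array/DataFrame
``(time, event)``.

Four estimators exist per outcome type, mirroring the analyses usually
compared: unadjusted (marginal estimand, no covariates), IPTW (marginal
estimand via treatment weighting), standardized / simulation-marginalized
(marginal estimand *with* covariate adjustment -- the efficient choice), and
conditional (the covariate-conditional estimand; a different quantity, not a
different estimator of the same one).

After ``fit``, ``estimate_`` holds the point estimate and ``result_`` a full
:class:`~marginalize.results.Estimate`.  ``bootstrap_inference`` re-runs the
whole procedure on row resamples and adds ``se_``, ``ci_low_``, ``ci_high_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .datasets import BinaryDataset, SurvivalDataset
from .hazard import MarginalHRConfig, marginal_log_hr
from .iptw import fit_propensity, iptw_log_hr, iptw_log_or
from .inference import bootstrap
from .odds import marginal_log_or, standardized_risk
from .results import Estimate
from .survival import fit_cox, fit_logistic

__all__ = [
    "UnadjustedLogOR",
    "IPTWLogOR",
    "StandardizedLogOR",
    "ConditionalLogOR",
    "UnadjustedLogHR",
    "IPTWLogHR",
    "SimulatedMarginalLogHR",
    "ConditionalLogHR",
]


def _split_exposure(X, exposure_col):
    if isinstance(X, pd.DataFrame):
        if isinstance(exposure_col, str):
            pos = list(X.columns).index(exposure_col)
        else:
            pos = int(exposure_col)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        pos = int(exposure_col)
    exposure = arr[:, pos]
    covariates = np.delete(arr, pos, axis=1)
    return exposure, covariates


def _as_time_event(y):
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(dtype=float), y["event"].to_numpy()
    arr = np.asarray(y)
    if arr.dtype.names:  # structured, sksurv-style (event, time) in any order
        names = {n.lower(): n for n in arr.dtype.names}
        ev = arr[names.get("event", arr.dtype.names[0])]
        t = arr[names.get("time", arr.dtype.names[1])]
        return np.asarray(t, dtype=float), np.asarray(ev).astype(int)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError(
        "survival y must be a structured (event, time) array, a (time, event) "
        "two-column array, or a DataFrame with 'time' and 'event' columns"
    )


class _EffectEstimator(BaseEstimator):
    """Shared fit plumbing; subclasses implement ``_compute(data, seed)``."""

    _survival = False
    estimand = ""
    method = ""

    def _dataset(self, X, y):
        exposure, covariates = _split_exposure(X, self.exposure_col)
        if self._survival:
            time, event = _as_time_event(y)
            return SurvivalDataset(time, event, exposure.astype(int), covariates)
        return BinaryDataset(np.asarray(y).astype(int), exposure.astype(int), covariates)

    def _seed(self):
        rs = getattr(self, "random_state", None)
        return 0 if rs is None else int(rs)

    def fit(self, X, y):
        data = self._dataset(X, y)
        self.n_features_in_ = 1 + data.n_covariates
        self.estimate_ = float(self._compute(data, self._seed()))
        self.result_ = Estimate(
            estimand=self.estimand, estimate=self.estimate_, method=self.method
        )
        return self

    def bootstrap_inference(
        self, X, y, B: int = 1000, seed: int = 0, n_jobs: int = 1,
        stratify_by_exposure: bool = False,
    ):
        """Nonparametric bootstrap of the full procedure; stores ``se_``,
        ``ci_low_``, ``ci_high_`` and returns the BootstrapResult."""
        if not hasattr(self, "estimate_"):
            self.fit(X, y)
        data = self._dataset(X, y)
        worker = clone(self)  # replicate fits must not clobber this fit's state
        res = bootstrap(
            worker._compute, data, B=B, seed=seed, n_jobs=n_jobs,
            stratify_by_exposure=stratify_by_exposure,
        )
        self.bootstrap_ = res
        self.se_, self.ci_low_, self.ci_high_ = res.se, res.ci_low, res.ci_high
        self.result_ = Estimate(
            estimand=self.estimand, estimate=self.estimate_, method=self.method,
            se=res.se, ci_low=res.ci_low, ci_high=res.ci_high,
            meta={"B": B, "seed": seed, "n_failed": res.n_failed},
        )
        return res


# ----------------------------- binary outcome ------------------------------


class UnadjustedLogOR(_EffectEstimator):
    """Plain logistic regression on exposure only: the usual marginal
    (associational) log odds ratio; causal only under randomization."""

    estimand = "log_or_marginal"
    method = "unadjusted"

    def __init__(self, exposure_col=0):
        self.exposure_col = exposure_col

    def _compute(self, data, seed):
        return fit_logistic(data, adjust=False).exposure_coef


class ConditionalLogOR(_EffectEstimator):
    """Covariate-adjusted logistic regression; reports the exposure
    coefficient, i.e. the *conditional* log odds ratio given the covariates."""

    estimand = "log_or_conditional"
    method = "conditional"

    def __init__(self, exposure_col=0):
        self.exposure_col = exposure_col

    def _compute(self, data, seed):
        fit = fit_logistic(data, adjust=True)
        self.model_fit_ = fit
        return fit.exposure_coef


class StandardizedLogOR(_EffectEstimator):
    """Covariate-adjusted estimator of the *marginal* causal log odds ratio:
    standardize the adjusted fit's predicted risks over the empirical (or
    reweighted) covariate distribution and contrast the log odds."""

    estimand = "log_or_marginal"
    method = "adjusted_marginal"

    def __init__(self, exposure_col=0, weights=None):
        self.exposure_col = exposure_col
        self.weights = weights

    def _compute(self, data, seed):
        fit = fit_logistic(data, adjust=True)
        est = marginal_log_or(fit, data, weights=self.weights)
        self.model_fit_ = fit
        self.risk0_ = standardized_risk(fit, data, 0, self.weights)
        self.risk1_ = standardized_risk(fit, data, 1, self.weights)
        return est.estimate


class IPTWLogOR(_EffectEstimator):
    """Inverse-probability-of-treatment-weighted unadjusted logistic
    estimator of the marginal causal log odds ratio."""

    estimand = "log_or_marginal"
    method = "iptw"

    def __init__(self, exposure_col=0, stabilized=False, weight_cap=0.05):
        self.exposure_col = exposure_col
        self.stabilized = stabilized
        self.weight_cap = weight_cap

    def _compute(self, data, seed):
        self.propensity_ = fit_propensity(data.covariates, data.exposure, self.stabilized)
        return iptw_log_or(data, self.stabilized, self.weight_cap).estimate


# --------------------------- time-to-event outcome -------------------------


class UnadjustedLogHR(_EffectEstimator):
    """Plain Cox regression on exposure only: the usual marginal
    (associational) log hazard ratio; causal only under randomization."""

    _survival = True
    estimand = "log_hr_marginal"
    method = "unadjusted"

    def __init__(self, exposure_col=0, ties="efron"):
        self.exposure_col = exposure_col
        self.ties = ties

    def _compute(self, data, seed):
        return fit_cox(data, adjust=False, ties=self.ties, with_baseline=False).exposure_coef


class ConditionalLogHR(_EffectEstimator):
    """Covariate-adjusted Cox regression; reports the exposure coefficient,
    i.e. the *conditional* log hazard ratio given the covariates."""

    _survival = True
    estimand = "log_hr_conditional"
    method = "conditional"

    def __init__(self, exposure_col=0, ties="efron"):
        self.exposure_col = exposure_col
        self.ties = ties

    def _compute(self, data, seed):
        fit = fit_cox(data, adjust=True, ties=self.ties, with_baseline=False)
        self.model_fit_ = fit
        return fit.exposure_coef


class IPTWLogHR(_EffectEstimator):
    """IPT-weighted unadjusted Cox estimator of the marginal causal log HR."""

    _survival = True
    estimand = "log_hr_marginal"
    method = "iptw"

    def __init__(self, exposure_col=0, stabilized=False, weight_cap=0.05, ties="efron"):
        self.exposure_col = exposure_col
        self.stabilized = stabilized
        self.weight_cap = weight_cap
        self.ties = ties

    def _compute(self, data, seed):
        self.propensity_ = fit_propensity(data.covariates, data.exposure, self.stabilized)
        return iptw_log_hr(data, self.stabilized, self.weight_cap, self.ties).estimate


class SimulatedMarginalLogHR(_EffectEstimator):
    """Covariate-adjusted estimator of the *marginal* causal log hazard ratio
    by Monte-Carlo marginalization of a conditional Cox fit, mimicking the
    study's censoring process (see :mod:`marginalize.hazard`).

    Parameters
    ----------
    m : simulated subjects per arm (2m records); larger m, less MC error.
    censoring : 'mimic' (default), 'none', 'admin_only' or 'external_curves'.
    time_frame : 'study' or a shorter horizon in time units.
    weights : optional covariate-distribution weights for the standardized
        curves (marginalize over a reference population).
    random_state : seed for the internal simulation.
    """

    _survival = True
    estimand = "log_hr_marginal"
    method = "adjusted_marginal"

    def __init__(
        self,
        exposure_col=0,
        m=5000,
        censoring="mimic",
        time_frame="study",
        sampler="inverse_transform",
        ties="efron",
        weights=None,
        external_curves=None,
        random_state=0,
    ):
        self.exposure_col = exposure_col
        self.m = m
        self.censoring = censoring
        self.time_frame = time_frame
        self.sampler = sampler
        self.ties = ties
        self.weights = weights
        self.external_curves = external_curves
        self.random_state = random_state

    def _config(self, seed):
        return MarginalHRConfig(
            m=self.m,
            censoring=self.censoring,
            time_frame=self.time_frame,
            seed=int(seed),
            sampler=self.sampler,
            ties=self.ties,
            external_curves=self.external_curves,
        )

    def _compute(self, data, seed):
        est = marginal_log_hr(data, self._config(seed), weights=self.weights)
        self.meta_ = est.meta
        return est.estimate
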