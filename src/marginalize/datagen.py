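"""Synthetic data generators for the simulation-study scenarios.

Each scenario draws a single standard-normal baseline covariate C that stays
fixed, within individual, across replications (only exposure and outcome are
redrawn).  Exposure is Bernoulli(0.5) in the randomized-trial scenarios and
Bernoulli(expit(C)) in the observational ones, making C a confounder.

Binary outcomes follow a logistic model
``logit Pr(Y=1 | X, C) = mu + nu*X + gamma*C`` with mu = 1.

Event times follow a conditional proportional-hazards model with Weibull
baseline cumulative hazard ``H0(t) = scale * t^shape`` (scale 0.1, shape 1.5),
so the linear-predictor coefficients are exactly conditional log hazard
ratios.  Subjects enter uniformly over a 2-year recruitment window and are
administratively censored 10 years after the start of recruitment; the
analysis time-scale is time since each subject's own entry, so censoring times
fall in [8, 10] years and entry plays no other role (no left truncation).

The four named scenarios set the (treatment, covariate) coefficients to
(0,1), (1,0) and (1,1) under randomization, and (1,1) with confounded
exposure, written ``(1,1)*``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .datasets import BinaryDataset, SurvivalDataset

__all__ = [
    "ScenarioSpec",
    "SCENARIO_LABELS",
    "simulate_covariates",
    "simulate_binary",
    "simulate_tte",
    "simulate",
]

SCENARIO_LABELS = ("(0,1)", "(1,0)", "(1,1)", "(1,1)*")

_LABEL_COEFS = {
    "(0,1)": (0.0, 1.0, "rct"),
    "(1,0)": (1.0, 0.0, "rct"),
    "(1,1)": (1.0, 1.0, "rct"),
    "(1,1)*": (1.0, 1.0, "observational"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one data-generating mechanism."""

    outcome: str  # 'binary' or 'tte'
    exposure_mech: str = "rct"  # 'rct' or 'observational'
    treatment_effect: float = 1.0  # nu (binary) or lambda (tte)
    covariate_effect: float = 1.0  # gamma (binary) or rho (tte)
    n: int = 1000
    seed: int = 0
    intercept: float = 1.0  # mu in the binary-outcome model
    weibull_scale: float = 0.1
    weibull_shape: float = 1.5
    recruitment_window: float = 2.0
    admin_end: float = 10.0

    def __post_init__(self) -> None:
        if self.outcome not in ("binary", "tte"):
            raise ValueError("outcome must be 'binary' or 'tte'")
        if self.exposure_mech not in ("rct", "observational"):
            raise ValueError("exposure_mech must be 'rct' or 'observational'")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        if not 0 < self.recruitment_window < self.admin_end:
            raise ValueError("need 0 < recruitment_window < admin_end")

    @classmethod
    def from_label(cls, outcome: str, label: str, **kwargs) -> "ScenarioSpec":
        """Build one of the four named scenarios, e.g. ``('tte', '(1,1)*')``."""
        try:
            nu, gamma, mech = _LABEL_COEFS[label]
        except KeyError:
            raise ValueError(
                f"unknown scenario label {label!r}; expected one of {SCENARIO_LABELS}"
            ) from None
        return cls(
            outcome=outcome,
            exposure_mech=mech,
            treatment_effect=nu,
            covariate_effect=gamma,
            **kwargs,
        )

    @property
    def label(self) -> str:
        tag = f"({self.treatment_effect:g},{self.covariate_effect:g})"
        return tag + ("*" if self.exposure_mech == "observational" else "")

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


_COVARIATE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def simulate_covariates(n: int, seed: int) -> np.ndarray:
    """Standard-normal covariate draws, cached per (n, seed) so that all
    replications of a simulation study share the same covariate vector."""
    if n < 1:
        raise ValueError("n must be >= 1")
    key = (int(n), int(seed))
    if key not in _COVARIATE_CACHE:
        rng = np.random.default_rng(seed)
        _COVARIATE_CACHE[key] = rng.standard_normal(n)
    return _COVARIATE_CACHE[key].copy()


def _draw_exposure(spec: ScenarioSpec, covariates: np.ndarray, rng) -> np.ndarray:
    if spec.exposure_mech == "rct":
        p = np.full(len(covariates), 0.5)
    else:
        p = expit(covariates)
    return (rng.random(len(covariates)) < p).astype(int)


def simulate_binary(
    spec: ScenarioSpec, covariates: np.ndarray | None = None, seed: int | None = None
) -> BinaryDataset:
    """Draw exposure and a Bernoulli outcome given the (fixed) covariates."""
    if covariates is None:
        covariates = simulate_covariates(spec.n, spec.seed)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim != 1 or len(covariates) != spec.n:
        raise ValueError("covariates must be a length-n vector")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = _draw_exposure(spec, covariates, rng)
    p = expit(spec.intercept + spec.treatment_effect * x + spec.covariate_effect * covariates)
    y = (rng.random(spec.n) < p).astype(int)
    return BinaryDataset(y, x, covariates)


def simulate_tte(
    spec: ScenarioSpec, covariates: np.ndarray | None = None, seed: int | None = None
) -> SurvivalDataset:
    """Draw exposure and a right-censored Weibull event time.

    The latent time T has cumulative hazard
    ``H(t | X, C) = scale * t^shape * exp(lambda*X + rho*C)`` and is drawn by
    inverse transform; the censoring time is ``admin_end - entry`` with entry
    uniform on (0, recruitment_window).
    """
    if covariates is None:
        covariates = simulate_covariates(spec.n, spec.seed)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim != 1 or len(covariates) != spec.n:
        raise ValueError("covariates must be a length-n vector")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = _draw_exposure(spec, covariates, rng)
    entry = rng.random(spec.n) * spec.recruitment_window
    u = rng.random(spec.n)
    lp = spec.treatment_effect * x + spec.covariate_effect * covariates
    latent = (-np.log(u) / (spec.weibull_scale * np.exp(lp))) ** (1.0 / spec.weibull_shape)
    cens = spec.admin_end - entry
    time = np.minimum(latent, cens)
    event = (latent <= cens).astype(int)
    return SurvivalDataset(time, event, x, covariates)


def simulate(
    spec: ScenarioSpec, covariates: np.ndarray | None = None, seed: int | None = None
):
    """Dispatch to :func:`simulate_binary` or :func:`simulate_tte`."""
    fn = simulate_binary if spec.outcome == "binary" else simulate_tte
    return fn(spec, covariates, seed)
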