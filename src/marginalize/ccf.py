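"""Characteristic collapsibility functions (CCFs) and an exact marginalization oracle.

For a link function ``f`` mapping outcome probabilities to the scale of the
linear predictor, and a conditional treatment effect ``nu`` on that scale, the
CCF

    g_nu(p) = f^{-1}(f(p) + nu)

maps the untreated outcome probability (at a given covariate value) to the
treated one.  Whether a marginal (covariate-averaged) effect measure equals the
constant conditional effect -- collapsibility -- is governed by the shape of
g_nu via Jensen's inequality: a linear CCF means collapsible, a concave CCF
(positive ``nu``, logit/cloglog/probit links) means the marginal effect is
attenuated toward the null, a convex CCF (negative ``nu``) means the reverse.

Rates from discrete-time survival models condition on past survival; removing
that conditioning changes the effective link, so rate differences and rate
ratios are noncollapsible even though risk differences and risk ratios are not.
:func:`rate_ccf_eval` computes the implied risk-scale CCF for such models.

:func:`marginal_effect_by_integration` integrates the conditional risk model
over a covariate distribution exactly (adaptive quadrature).  It serves as the
independent oracle against which the sample-based standardization estimators
are checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import expit, logit

__all__ = [
    "Link",
    "LINKS",
    "get_link",
    "ccf_eval",
    "classify_ccf",
    "RateModelSpec",
    "rate_ccf_eval",
    "marginal_effect_by_integration",
]


@dataclass(frozen=True)
class Link:
    """A link function ``f`` with its inverse.

    ``probability_respecting`` is True when ``f^{-1}`` maps all reals into
    [0, 1]; the identity, log and complementary-log links do not respect
    probability bounds and their CCFs can leave (0, 1).
    """

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    probability_respecting: bool = True


_norm = stats.norm

LINKS: dict[str, Link] = {
    "identity": Link("identity", lambda p: p, lambda z: z, probability_respecting=False),
    "log": Link("log", np.log, np.exp, probability_respecting=False),
    "logit": Link("logit", logit, expit),
    "cloglog": Link(
        "cloglog",
        lambda p: np.log(-np.log1p(-np.asarray(p, dtype=float))),
        lambda z: -np.expm1(-np.exp(z)),
    ),
    "probit": Link("probit", _norm.ppf, _norm.cdf),
    # log of the survival fraction 1-p; the risk-scale link implied by
    # additive hazards models (collapsible: its CCF is affine).
    "complementary-log": Link(
        "complementary-log",
        lambda p: np.log1p(-np.asarray(p, dtype=float)),
        lambda z: -np.expm1(z),
        probability_respecting=False,
    ),
}

# Links whose CCF is affine in p for every nu, hence collapsible.
_LINEAR_LINKS = frozenset({"identity", "log", "complementary-log"})


def get_link(link: str | Link) -> Link:
    if isinstance(link, Link):
        return link
    try:
        return LINKS[link]
    except KeyError:
        raise ValueError(
            f"unknown link {link!r}; available: {sorted(LINKS)}"
        ) from None


def ccf_eval(link: str | Link, nu: float, p):
    """Evaluate the CCF ``g_nu(p) = f^{-1}(f(p) + nu)``.

    Parameters
    ----------
    link : str or Link
        Link function ``f``.
    nu : float
        Conditional effect on the linear-predictor scale.
    p : float or array-like
        Untreated outcome probability, strictly inside (0, 1).

    Returns
    -------
    Treated outcome probability (same shape as ``p``).  For links that do not
    respect probability bounds the result can fall outside (0, 1); a warning
    is issued and the value returned unchanged.
    """
    link = get_link(link)
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0.0) | (p_arr >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not np.isfinite(nu):
        raise ValueError("nu must be finite")
    out = link.inverse(link.forward(p_arr) + nu)
    if np.any((np.asarray(out) <= 0.0) | (np.asarray(out) >= 1.0)):
        warnings.warn(
            f"CCF value outside (0, 1) for link {link.name!r}; "
            "this link does not respect probability bounds",
            RuntimeWarning,
            stacklevel=2,
        )
    return out if np.ndim(p) else float(out)


def classify_ccf(
    link: str | Link,
    nu: float,
    *,
    n_grid: int = 512,
    tol: float = 1e-8,
) -> str:
    """Classify the CCF as ``'linear'``, ``'concave'`` or ``'convex'``.

    The classification samples g_nu on ``n_grid`` equispaced points in
    (0.001, 0.999) and inspects the sign of the second differences with
    absolute tolerance ``tol``.  Links with an affine CCF (identity, log,
    complementary-log) and ``nu=0`` for any link are linear.
    """
    link = get_link(link)
    if not np.isfinite(nu):
        raise ValueError("nu must be finite")
    if nu == 0.0 or link.name in _LINEAR_LINKS:
        return "linear"
    p = np.linspace(0.001, 0.999, n_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g = np.asarray(ccf_eval(link, nu, p))
    d2 = np.diff(g, n=2)
    if np.all(np.abs(d2) <= tol):
        return "linear"
    if np.all(d2 <= tol):
        return "concave"
    if np.all(d2 >= -tol):
        return "convex"
    raise RuntimeError(
        f"CCF for link {link.name!r}, nu={nu} changes curvature on (0,1); "
        "classification is not well defined"
    )


def _constant_baseline(tau: int) -> np.ndarray:
    # constant per-interval rate such that total untreated risk over the
    # tau intervals is 0.5
    r = 1.0 - 0.5 ** (1.0 / tau)
    return np.full(tau, r)


@dataclass(frozen=True)
class RateModelSpec:
    """Discrete-time rate model: ``tau`` intervals, a rate-scale link and a
    treatment effect ``lam`` on the rate linear predictor.

    ``baseline_rates`` are the untreated per-interval event rates conditional
    on survival to the start of each interval.  When omitted, a constant rate
    calibrated so the total untreated risk is 0.5 is used.
    """

    tau: int
    interval_index: int
    link: str | Link = "log"
    lam: float = 0.0
    baseline_rates: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be a positive integer")
        if not 1 <= self.interval_index <= self.tau:
            raise ValueError("interval_index must lie in 1..tau")
        rates = (
            _constant_baseline(self.tau)
            if self.baseline_rates is None
            else np.asarray(self.baseline_rates, dtype=float)
        )
        if rates.shape != (self.tau,):
            raise ValueError("baseline_rates must have length tau")
        if np.any((rates <= 0.0) | (rates >= 1.0)):
            raise ValueError("baseline_rates must lie strictly inside (0, 1)")
        object.__setattr__(self, "baseline_rates", rates)

    def treated_rates(self) -> np.ndarray:
        """Per-interval treated rates: the link shift applied interval-wise."""
        link = get_link(self.link)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.asarray(link.inverse(link.forward(self.baseline_rates) + self.lam))
        bad = np.flatnonzero((out <= 0.0) | (out >= 1.0))
        if bad.size:
            raise ValueError(
                f"treated rate outside (0, 1) in interval {bad[0] + 1} "
                f"(link={link.name!r}, lam={self.lam})"
            )
        return out


def rate_ccf_eval(spec: RateModelSpec, p0: float) -> float:
    """Risk-scale CCF implied by a discrete-time rate model.

    Maps the *unconditional* probability ``p0`` of an event in interval
    ``spec.interval_index`` under no treatment to the corresponding
    unconditional probability under treatment: (i) divide by the untreated
    survival through the preceding intervals to recover the conditional rate,
    (ii) shift by ``lam`` on the rate-link scale, (iii) multiply by the
    treated survival through the preceding intervals.

    For the first interval there is no conditioning on past survival and the
    map reduces exactly to :func:`ccf_eval` on the rate link.
    """
    link = get_link(spec.link)
    l = spec.interval_index
    r0 = np.asarray(spec.baseline_rates)
    r1 = spec.treated_rates()
    surv0 = float(np.prod(1.0 - r0[: l - 1]))
    surv1 = float(np.prod(1.0 - r1[: l - 1]))
    if surv0 <= 0.0:
        raise ValueError("untreated survival through preceding intervals is zero")
    rate0 = p0 / surv0
    if not 0.0 < rate0 < 1.0:
        raise ValueError(
            f"p0={p0} implies a conditional rate {rate0} outside (0, 1) "
            f"in interval {l}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rate1 = float(link.inverse(link.forward(rate0) + spec.lam))
    if not 0.0 < rate1 < 1.0:
        raise ValueError(
            f"treated rate outside (0, 1) in interval {l} "
            f"(link={link.name!r}, lam={spec.lam})"
        )
    return rate1 * surv1


def marginal_effect_by_integration(
    link: str | Link,
    intercept: float,
    nu: float,
    covariate_coef: float,
    covariate_dist,
    *,
    tol: float = 1e-10,
) -> float:
    """Marginal effect on the link scale by exact integration over a covariate.

    Integrates the conditional risk ``f^{-1}(intercept + nu*x + coef*c)`` over
    the covariate distribution for x=1 and x=0 and returns
    ``f(pbar_1) - f(pbar_0)`` -- for the logit link, the marginal log odds
    ratio.  This is the closed-form counterpart of the sample standardization
    estimators and is used as their oracle.

    Parameters
    ----------
    covariate_dist : scipy.stats frozen distribution
        e.g. ``scipy.stats.uniform(-10, 20)`` or ``scipy.stats.norm(0, 1)``.
        Unbounded supports are truncated at mean +/- 8 sd.
    """
    link = get_link(link)
    lo, hi = covariate_dist.support()
    if not np.isfinite(lo):
        lo = covariate_dist.mean() - 8.0 * covariate_dist.std()
    if not np.isfinite(hi):
        hi = covariate_dist.mean() + 8.0 * covariate_dist.std()

    def mean_risk(x: int) -> float:
        def integrand(c: float) -> float:
            return float(link.inverse(intercept + nu * x + covariate_coef * c)) * float(
                covariate_dist.pdf(c)
            )

        val, err = integrate.quad(integrand, lo, hi, epsabs=tol, limit=500)
        if err > max(100.0 * tol, 1e-8):
            raise RuntimeError(
                f"quadrature did not converge: achieved abs error {err:g}"
            )
        return val

    pbar1, pbar0 = mean_risk(1), mean_risk(0)
    for pbar in (pbar0, pbar1):
        if not 0.0 < pbar < 1.0:
            warnings.warn(
                f"averaged risk {pbar:g} outside (0, 1) for link {link.name!r}",
                RuntimeWarning,
                stacklevel=2,
            )
    return float(link.forward(pbar1) - link.forward(pbar0))
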