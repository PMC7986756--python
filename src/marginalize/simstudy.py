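"""Simulation-study harness: scenarios x methods with Monte-Carlo errors.

Performance measures follow the standard simulation-study conventions: the
across-replication sample mean and standard deviation of each estimator are
the estimated mean and empirical SE, with Monte-Carlo errors

    MCerr(mean)  = empSE / sqrt(n_sim)
    MCerr(empSE) = empSE / sqrt(2 * (n_sim - 1)).

The covariate vector is drawn once per (n, base_seed) and shared by all
replications of a scenario; exposure and outcome are redrawn each replication
from deterministic per-replication substreams, so runs are reproducible and
resumable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datagen import SCENARIO_LABELS, ScenarioSpec, simulate, simulate_covariates
from .hazard import MarginalHRConfig, marginal_log_hr
from .iptw import iptw_log_hr, iptw_log_or
from .odds import marginal_log_or
from .survival import fit_cox, fit_logistic

__all__ = [
    "PerformanceSummary",
    "mc_errors",
    "method_registry",
    "run_scenario",
    "reproduce_table1",
    "format_summaries",
]

METHODS = ("unadjusted", "iptw", "adjusted_marginal", "conditional")


@dataclass(frozen=True)
class PerformanceSummary:
    scenario: str
    method: str
    mean: float
    mean_mc_error: float
    emp_se: float
    emp_se_mc_error: float
    n_sim: int


def mc_errors(estimates) -> tuple[float, float, float, float]:
    """(mean, MC error of mean, empirical SE, MC error of empirical SE)."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    n = len(est)
    if n < 2:
        raise ValueError("need at least two estimates")
    mean = float(est.mean())
    emp_se = float(est.std(ddof=1))
    return mean, emp_se / np.sqrt(n), emp_se, emp_se / np.sqrt(2 * (n - 1))


def method_registry(
    outcome: str, hr_config: MarginalHRConfig | None = None
) -> dict[str, Callable]:
    """Callables ``(data, seed) -> float`` for the four standard analyses."""
    if outcome == "binary":
        return {
            "unadjusted": lambda d, s: fit_logistic(d, adjust=False).exposure_coef,
            "iptw": lambda d, s: iptw_log_or(d).estimate,
            "adjusted_marginal": lambda d, s: marginal_log_or(data=d).estimate,
            "conditional": lambda d, s: fit_logistic(d, adjust=True).exposure_coef,
        }
    cfg = hr_config or MarginalHRConfig()

    def _adj_marginal(d, s):
        return marginal_log_hr(d, replace(cfg, seed=int(s))).estimate

    return {
        "unadjusted": lambda d, s: fit_cox(
            d, adjust=False, with_baseline=False
        ).exposure_coef,
        "iptw": lambda d, s: iptw_log_hr(d).estimate,
        "adjusted_marginal": _adj_marginal,
        "conditional": lambda d, s: fit_cox(
            d, adjust=True, with_baseline=False
        ).exposure_coef,
    }


def _rep_seed(base_seed: int, rep: int) -> int:
    return int((base_seed * 1_000_003 + rep) % (2**31 - 1))


def run_scenario(
    spec: ScenarioSpec,
    methods: Sequence[str] | Mapping[str, Callable] = METHODS,
    n_sim: int = 1000,
    base_seed: int = 0,
    hr_config: MarginalHRConfig | None = None,
    checkpoint_path: str | None = None,
) -> tuple[pd.DataFrame, list[PerformanceSummary]]:
    """Run one data-generating mechanism for ``n_sim`` replications.

    Returns the per-replication estimates (one column per method; failed
    replications are NaN) and the summaries.  With ``checkpoint_path``,
    completed replications are appended to a CSV as they finish and skipped
    on restart.
    """
    if isinstance(methods, Mapping):
        fns = dict(methods)
    else:
        registry = method_registry(spec.outcome, hr_config)
        unknown = set(methods) - set(registry)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        fns = {name: registry[name] for name in methods}

    covariates = simulate_covariates(spec.n, base_seed)
    done: dict[int, dict[str, float]] = {}
    if checkpoint_path and os.path.exists(checkpoint_path):
        prev = pd.read_csv(checkpoint_path)
        for rep, grp in prev.groupby("rep"):
            done[int(rep)] = dict(zip(grp["method"], grp["estimate"]))

    rows = []
    handle = open(checkpoint_path, "a") if checkpoint_path else None
    try:
        if handle is not None and not done and handle.tell() == 0:
            handle.write("rep,method,estimate\n")
        for rep in range(n_sim):
            if rep in done and set(done[rep]) >= set(fns):
                rows.append({"rep": rep, **done[rep]})
                continue
            data = simulate(spec, covariates, seed=[base_seed, 1, rep])
            rep_seed = _rep_seed(base_seed, rep)
            row = {"rep": rep}
            for name, fn in fns.items():
                try:
                    row[name] = float(fn(data, rep_seed))
                except Exception:
                    row[name] = np.nan
                if handle is not None:
                    handle.write(f"{rep},{name},{row[name]}\n")
            if handle is not None:
                handle.flush()
            rows.append(row)
    finally:
        if handle is not None:
            handle.close()

    estimates = pd.DataFrame(rows).set_index("rep")[list(fns)]
    summaries = []
    for name in fns:
        if np.isfinite(estimates[name]).sum() < 2:
            summaries.append(
                PerformanceSummary(
                    scenario=spec.label, method=name, mean=np.nan,
                    mean_mc_error=np.nan, emp_se=np.nan, emp_se_mc_error=np.nan,
                    n_sim=int(np.isfinite(estimates[name]).sum()),
                )
            )
            continue
        mean, mmc, se, semc = mc_errors(estimates[name])
        summaries.append(
            PerformanceSummary(
                scenario=spec.label, method=name, mean=mean, mean_mc_error=mmc,
                emp_se=se, emp_se_mc_error=semc,
                n_sim=int(np.isfinite(estimates[name]).sum()),
            )
        )
    return estimates, summaries


def reproduce_table1(
    n_sim: int = 1000,
    base_seed: int = 0,
    m_per_arm: Sequence[int] = (500, 2500, 5000),
    n: int = 1000,
    outcomes: Sequence[str] = ("binary", "tte"),
    checkpoint_dir: str | None = None,
) -> pd.DataFrame:
    """Full scenarios-by-methods grid, including the extra simulated-sample
    sizes (2m) for the simulation-marginalized hazard-ratio estimator."""
    records = []
    for outcome in outcomes:
        for label in SCENARIO_LABELS:
            spec = ScenarioSpec.from_label(outcome, label, n=n)
            if outcome == "binary":
                fns = method_registry("binary")
            else:
                fns = {
                    k: v
                    for k, v in method_registry(
                        "tte", MarginalHRConfig(m=m_per_arm[0])
                    ).items()
                    if k != "adjusted_marginal"
                }
                for m in m_per_arm:
                    cfg = MarginalHRConfig(m=m)

                    def _adj(d, s, cfg=cfg):
                        return marginal_log_hr(d, replace(cfg, seed=int(s))).estimate

                    fns[f"adjusted_marginal[2m={2 * m}]"] = _adj
            ckpt = (
                os.path.join(checkpoint_dir, f"{outcome}_{label.replace('*', 'obs')}.csv")
                if checkpoint_dir
                else None
            )
            _, summaries = run_scenario(
                spec, fns, n_sim=n_sim, base_seed=base_seed, checkpoint_path=ckpt
            )
            for s in summaries:
                records.append(
                    {
                        "outcome": outcome,
                        "scenario": s.scenario,
                        "method": s.method,
                        "mean": s.mean,
                        "mean_mc_error": s.mean_mc_error,
                        "emp_se": s.emp_se,
                        "emp_se_mc_error": s.emp_se_mc_error,
                        "n_sim": s.n_sim,
                    }
                )
    return pd.DataFrame(records)


def format_summaries(df: pd.DataFrame) -> str:
    """Fixed-width text rendering of a summary table."""
    lines = []
    header = f"{'outcome':<8} {'scenario':<8} {'method':<28} {'mean (MC err)':<18} {'emp SE (MC err)':<18}"
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in df.iterrows():
        lines.append(
            f"{r['outcome']:<8} {r['scenario']:<8} {r['method']:<28} "
            f"{r['mean']:.2f} ({r['mean_mc_error']:.4f})   "
            f"{r['emp_se']:.2f} ({r['emp_se_mc_error']:.4f})"
        )
    return "\n".join(lines)
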