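"""Result containers shared by the estimators."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["Estimate"]


@dataclass
class Estimate:
    """A point estimate of a log OR / log HR estimand, with optional
    bootstrap standard error and percentile confidence interval."""

    estimand: str  # log_or_marginal / log_or_conditional / log_hr_marginal / log_hr_conditional
    estimate: float
    method: str  # unadjusted / iptw / adjusted_marginal / conditional
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.ci_high):
                raise ValueError("ci_low must not exceed ci_high")
            if not (self.ci_low <= self.estimate <= self.ci_high):
                # percentile intervals can exclude the point estimate only
                # under extreme skew; surface it rather than fail
                warnings.warn(
                    "point estimate lies outside the percentile CI "
                    f"[{self.ci_low:g}, {self.ci_high:g}]; heavy skew in the "
                    "bootstrap distribution",
                    RuntimeWarning,
                    stacklevel=2,
                )

    def __repr__(self) -> str:  # compact, table-friendly
        parts = [f"{self.estimand}={self.estimate:.4f}", f"method={self.method}"]
        if self.se is not None:
            parts.append(f"se={self.se:.4f}")
        if self.ci_low is not None:
            parts.append(f"ci=[{self.ci_low:.4f}, {self.ci_high:.4f}]")
        return "Estimate(" + ", ".join(parts) + ")"
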