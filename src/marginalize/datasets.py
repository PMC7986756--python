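"""Subject-level data containers for the binary-outcome and survival analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BinaryDataset", "SurvivalDataset"]


def _as_covariate_matrix(covariates) -> np.ndarray:
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.ndim != 2:
        raise ValueError("covariates must be a vector or an (n, p) matrix")
    return c


def _check_binary(name: str, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return v.astype(int)


@dataclass(frozen=True)
class BinaryDataset:
    """Binary outcome, binary exposure and an (n, p) covariate matrix."""

    outcome: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", _check_binary("outcome", self.outcome))
        object.__setattr__(self, "exposure", _check_binary("exposure", self.exposure))
        object.__setattr__(self, "covariates", _as_covariate_matrix(self.covariates))
        n = len(self.outcome)
        if len(self.exposure) != n or self.covariates.shape[0] != n:
            raise ValueError("outcome, exposure and covariates must be aligned")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx) -> "BinaryDataset":
        idx = np.asarray(idx)
        return BinaryDataset(self.outcome[idx], self.exposure[idx], self.covariates[idx])

    def to_frame(self) -> pd.DataFrame:
        d = {"outcome": self.outcome, "exposure": self.exposure}
        for j in range(self.n_covariates):
            d[f"c{j + 1}"] = self.covariates[:, j]
        return pd.DataFrame(d)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome: str = "outcome",
        exposure: str = "exposure",
        covariates: list[str] | None = None,
    ) -> "BinaryDataset":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (outcome, exposure)]
        return cls(
            df[outcome].to_numpy(),
            df[exposure].to_numpy(),
            df[covariates].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored follow-up time (years since recruitment), event
    indicator, binary exposure and an (n, p) covariate matrix."""

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("time must be finite and strictly positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", _check_binary("event", self.event))
        object.__setattr__(self, "exposure", _check_binary("exposure", self.exposure))
        object.__setattr__(self, "covariates", _as_covariate_matrix(self.covariates))
        n = len(t)
        if len(self.event) != n or len(self.exposure) != n or self.covariates.shape[0] != n:
            raise ValueError("time, event, exposure and covariates must be aligned")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def flip_event_indicator(self) -> "SurvivalDataset":
        """Swap the roles of event and censoring (D* = 1 - D): being censored
        becomes the event of interest.  Used by the censoring-mimicry model."""
        return SurvivalDataset(self.time, 1 - self.event, self.exposure, self.covariates)

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.time[idx], self.event[idx], self.exposure[idx], self.covariates[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "event": self.event, "exposure": self.exposure}
        for j in range(self.n_covariates):
            d[f"c{j + 1}"] = self.covariates[:, j]
        return pd.DataFrame(d)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        exposure: str = "exposure",
        covariates: list[str] | None = None,
    ) -> "SurvivalDataset":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (time, event, exposure)]
        return cls(
            df[time].to_numpy(dtype=float),
            df[event].to_numpy(),
            df[exposure].to_numpy(),
            df[covariates].to_numpy(dtype=float),
        )
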