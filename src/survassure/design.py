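"""Core trial-design containers shared by all three survival models."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["TrialDesign", "AssuranceResult", "Curve"]


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm design with uniform accrual on (0, R) and total length T.

    Patients enter uniformly during the recruitment window ``(0, R)`` and are
    followed until calendar time ``T`` (administrative censoring); survival
    time is measured from each patient's entry.  ``alpha`` is the two-sided
    significance level of the planned test.
    """

    R: float
    T: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.R <= self.T:
            raise ValueError("need 0 < R <= T")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")

    @classmethod
    def balanced(cls, R: float, T: float, n_per_group: int, alpha: float = 0.05) -> "TrialDesign":
        return cls(R, T, n_per_group, n_per_group, alpha)

    @classmethod
    def from_total(cls, R: float, T: float, n_total: int, q1: float = 0.5, q2: float = 0.5, alpha: float = 0.05) -> "TrialDesign":
        if not (q1 > 0 and q2 > 0 and abs(q1 + q2 - 1) < 1e-9):
            raise ValueError("allocation proportions must be positive and sum to 1")
        n1 = int(round(n_total * q1))
        return cls(R, T, n1, n_total - n1, alpha)

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2

    @property
    def q1(self) -> float:
        return self.n1 / self.n_total

    @property
    def q2(self) -> float:
        return self.n2 / self.n_total

    def with_per_group(self, n: int) -> "TrialDesign":
        """Same design with ``n`` patients in each group."""
        return replace(self, n1=int(n), n2=int(n))


@dataclass(frozen=True)
class AssuranceResult:
    """Monte Carlo assurance estimate.

    ``prior_superiority`` is the prior probability that the experimental
    treatment is truly better — the cap the assurance approaches as the
    sample size grows ("you cannot beat the prior").
    """

    estimate: float
    se: float
    n_draws: int
    seed: Optional[int]
    prior_superiority: float
    model: str

    def __post_init__(self):
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("assurance estimate must lie in [0,1]")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "assurance": self.estimate,
            "mc_se": self.se,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "prior_superiority": self.prior_superiority,
        }


@dataclass(frozen=True)
class Curve:
    """Power and assurance as a function of per-group sample size."""

    n: np.ndarray
    assurance: np.ndarray
    assurance_se: np.ndarray
    power: Optional[np.ndarray] = None
    model: str = ""

    def to_frame(self):
        import pandas as pd

        cols = {"n_per_group": self.n}
        if self.power is not None:
            cols["power"] = self.power
        cols["assurance"] = self.assurance
        cols["assurance_se"] = self.assurance_se
        return pd.DataFrame(cols)
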