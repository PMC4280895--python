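"""Right-censored survival datasets: container, file IO and simulation."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._rng import as_generator

__all__ = [
    "SurvivalDataset",
    "simulate_survival_dataset",
    "load_example_control_data",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Observed (time, status) records; status 1 = event, 0 = right-censored."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event).astype(bool)
        if t.ndim != 1 or t.shape != e.shape or len(t) == 0:
            raise ValueError("need matching, non-empty time and status vectors")
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def total_time(self) -> float:
        """Total time at risk (exposure) across all records."""
        return float(self.time.sum())

    @property
    def censoring_times(self) -> np.ndarray:
        """Distinct censoring times, sorted ascending."""
        return np.unique(self.time[~self.event])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "status": self.event.astype(int)})

    def to_file(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        cols = {c.lower(): c for c in df.columns}
        tcol = cols.get("time", df.columns[0])
        scol = cols.get("status", cols.get("event", df.columns[1]))
        return cls(df[tcol].to_numpy(dtype=float), df[scol].to_numpy())

    @classmethod
    def from_file(cls, path) -> "SurvivalDataset":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        return cls.from_frame(df)


def simulate_survival_dataset(
    model: str,
    params: dict,
    n: int,
    R: float,
    T: float,
    rng_seed=None,
) -> SurvivalDataset:
    """Simulate a trial arm with uniform entry on (0, R) and censoring at T.

    ``model`` is ``"exponential"`` (params: ``rate``) or ``"weibull"``
    (params: ``shape``, ``scale`` under S(t) = exp(-scale * t**shape)).
    Times are on the patient clock (from entry); a patient entering at ``a``
    is censored at ``T - a`` if still event-free.  ``T = inf`` disables
    censoring.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_generator(rng_seed)
    if model == "exponential":
        rate = float(params["rate"])
        if rate <= 0:
            raise ValueError("rate must be positive")
        x = rng.exponential(1.0 / rate, n)
    elif model == "weibull":
        shape, scale = float(params["shape"]), float(params["scale"])
        if shape <= 0 or scale <= 0:
            raise ValueError("shape and scale must be positive")
        x = rng.weibull(shape, n) * scale ** (-1.0 / shape)
    else:
        raise ValueError(f"unknown model {model!r}")
    if np.isinf(T):
        return SurvivalDataset(x, np.ones(n, dtype=bool))
    entry = rng.uniform(0.0, R, n)
    follow_up = T - entry
    event = x <= follow_up
    observed = np.where(event, x, follow_up)
    return SurvivalDataset(observed, event)


def load_example_control_data() -> SurvivalDataset:
    """Eight right-censored observations from the classic product-limit
    illustration (Kaplan & Meier, 1958), shipped as the package's example
    control-arm dataset."""
    ref = resources.files("survassure").joinpath("datasets/km1958_control.tsv")
    with resources.as_file(ref) as path:
        return SurvivalDataset.from_file(path)
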