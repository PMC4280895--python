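"""Nonparametric posterior for the control survivor function.

The control arm's survivor function S1 is given a Dirichlet-process prior
with precision c0 and shape survivor G: the prior measure of [t, inf) is
c0 * G(t), so the probabilities of any partition of the time axis are
Dirichlet distributed with parameters c0 * (increments of 1 - G).

With right-censored data the Dirichlet posterior is not available directly,
so a two-block Gibbs sampler is used:

1. **Imputation** — conditional on the interval probabilities p, each
   censored observation in interval k is allocated to one of the later
   intervals with multinomial probabilities proportional to (p_{k+1}, ...).
2. **Conjugate update** — conditional on the completed event counts d', a
   new p is drawn from Dirichlet(alpha + d').

The partition merges the Simpson quadrature nodes (where the assurance
calculation needs S1) with the distinct censoring times (where the
imputation needs interval boundaries).  Although the quadrature nodes live
on [T - R, T], the partition is extended down to 0 so that observed event
and censoring times before T - R are representable; a final interval
(last cut, inf) catches the remaining mass.

Kaplan-Meier estimation (used both for exploratory comparison and to anchor
worked examples) is provided on the same dataset container, backed by
lifelines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from ._rng import as_generator
from .data import SurvivalDataset
from .prop_hazards import QuadratureGrid

__all__ = [
    "KaplanMeierEstimate",
    "kaplan_meier",
    "Partition",
    "build_partition",
    "DPPrior",
    "gibbs_impute_censored",
    "gibbs_update_p",
    "SurvivorDraws",
    "posterior_survivor_draws",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Right-continuous product-limit step function, evaluable at any t >= 0."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx + 1]
        return float(out) if out.ndim == 0 else out


def kaplan_meier(data: SurvivalDataset) -> KaplanMeierEstimate:
    """Product-limit estimator of the survivor function (events before
    censorings at tied times, the usual convention)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event.astype(int))
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    values = sf.to_numpy(dtype=float)
    keep = times > 0
    return KaplanMeierEstimate(times[keep], values[keep])


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Ordered cut points and per-interval data counts.

    Intervals are (0, cuts[0]], (cuts[0], cuts[1]], ..., (cuts[-1], inf):
    ``len(cuts) + 1`` intervals in total, the last being the open tail.
    ``d[k]`` and ``r[k]`` count the observed events and censored records in
    interval k.
    """

    cuts: np.ndarray
    d: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        cuts = np.asarray(self.cuts, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) + 1

    def interval_index(self, t):
        """Index k such that t lies in (cuts[k-1], cuts[k]] (tail for t
        beyond the last cut; interval 0 for t <= cuts[0])."""
        return np.searchsorted(self.cuts, np.asarray(t, dtype=float), side="left")

    def cut_index(self, t: float) -> int:
        """Position of a time that must coincide with a cut point."""
        i = int(np.searchsorted(self.cuts, t))
        if i >= len(self.cuts) or not math.isclose(self.cuts[i], t, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"time {t} is not a partition cut point")
        return i


def build_partition(
    grid: QuadratureGrid, data: SurvivalDataset, extra_cuts: Sequence[float] = ()
) -> Partition:
    """Merge quadrature nodes, distinct censoring times and any extra cut
    points into one partition, and tabulate the data counts per interval.

    Duplicate cut points (a censoring time equal to a node, say) are merged;
    a note is logged when that happens.
    """
    raw = np.concatenate([grid.nodes, data.censoring_times, np.asarray(extra_cuts, dtype=float)])
    raw = raw[raw > 0]
    cuts = np.unique(raw)
    merged = np.sort(raw)
    if len(merged) != len(cuts):
        logger.info("merged %d duplicate cut point(s) in the partition", len(merged) - len(cuts))
    # collapse near-duplicates from floating arithmetic
    keep = np.concatenate([[True], np.diff(cuts) > 1e-12])
    cuts = cuts[keep]
    n_int = len(cuts) + 1
    d = np.zeros(n_int, dtype=int)
    r = np.zeros(n_int, dtype=int)
    idx = np.searchsorted(cuts, data.time, side="left")
    for i, is_event in zip(idx, data.event):
        if is_event:
            d[i] += 1
        else:
            r[i] += 1
    return Partition(cuts, d, r)


# ---------------------------------------------------------------------------
# Dirichlet-process prior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DPPrior:
    """Dirichlet-process prior with precision c0 and shape survivor G.

    ``shape`` must be a proper survivor function (G(0) = 1, nonincreasing).
    The induced Dirichlet parameter for interval (a, b] is
    c0 * (G(a) - G(b)); the tail interval receives c0 * G(last cut).
    """

    c0: float
    shape: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError("precision c0 must be positive")

    @classmethod
    def exponential(cls, c0: float, rate: float) -> "DPPrior":
        if rate <= 0:
            raise ValueError("rate must be positive")
        return cls(c0, lambda t: np.exp(-rate * np.asarray(t, dtype=float)))

    @classmethod
    def exponential_anchor(cls, c0: float, t_anchor: float, s_anchor: float) -> "DPPrior":
        """Exponential shape through one elicited point, e.g. G(5) = 0.5
        gives rate ln(2)/5."""
        if not 0 < s_anchor < 1 or t_anchor <= 0:
            raise ValueError("anchor must satisfy 0 < s < 1 and t > 0")
        return cls.exponential(c0, -math.log(s_anchor) / t_anchor)

    def alphas(self, partition: Partition) -> np.ndarray:
        g = np.concatenate([[1.0], np.asarray(self.shape(partition.cuts), dtype=float)])
        alpha = self.c0 * np.concatenate([-np.diff(g), [g[-1]]])
        if np.any(alpha < -1e-12):
            raise ValueError("shape function is not a nonincreasing survivor")
        return np.clip(alpha, 0.0, None)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_impute_censored(p: np.ndarray, partition: Partition, rng_seed=None):
    """Allocate each censored record to a later interval, multinomially with
    probabilities proportional to the current interval masses.

    Returns ``(z, d_prime)`` where ``z[j, k]`` is the number of censored
    records from interval k imputed into interval j, and
    ``d_prime = d + column-sums of z`` are the completed event counts.
    """
    rng = as_generator(rng_seed)
    n_int = partition.n_intervals
    z = np.zeros((n_int, n_int), dtype=int)
    d_prime = partition.d.copy()
    for k in np.nonzero(partition.r)[0]:
        rk = partition.r[k]
        if k == n_int - 1:
            warnings.warn("censored record in the tail interval; event assigned to the tail")
            z[k, k] = rk
            d_prime[k] += rk
            continue
        tail = p[k + 1 :]
        total = tail.sum()
        if total <= 0:
            warnings.warn("no probability mass beyond a censored record; event assigned to the tail interval")
            z[-1, k] = rk
            d_prime[-1] += rk
            continue
        alloc = rng.multinomial(rk, tail / total)
        z[k + 1 :, k] = alloc
        d_prime[k + 1 :] += alloc
    return z, d_prime


def gibbs_update_p(d_prime: np.ndarray, alphas: np.ndarray, rng_seed=None) -> np.ndarray:
    """Conjugate Dirichlet draw of the interval probabilities."""
    conc = np.asarray(alphas, dtype=float) + np.asarray(d_prime, dtype=float)
    if np.all(conc <= 0):
        raise ValueError("all Dirichlet concentration parameters are zero")
    # numpy's dirichlet rejects exact zeros; a tiny floor leaves those
    # intervals with (numerically) zero mass, as the limit requires
    return as_generator(rng_seed).dirichlet(np.clip(conc, 1e-300, None))


# ---------------------------------------------------------------------------
# posterior survivor draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivorDraws:
    """Posterior samples of the control survivor at the quadrature nodes and
    at the anchor time t0, plus sampler metadata."""

    nodes: np.ndarray
    node_samples: np.ndarray
    t0: float
    t0_samples: np.ndarray
    seed: Optional[int]
    burn_in: int

    @property
    def n_draws(self) -> int:
        return self.node_samples.shape[0]

    def node_means(self) -> np.ndarray:
        return self.node_samples.mean(axis=0)


def posterior_survivor_draws(
    data: SurvivalDataset,
    prior: DPPrior,
    grid: QuadratureGrid,
    t0: float,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    rng_seed=None,
) -> SurvivorDraws:
    """Run the Gibbs sampler and return survivor draws at the grid nodes
    and at t0.

    The chain alternates censored-record imputation and the conjugate
    Dirichlet update, starting from the prior mean probabilities.  Each
    retained probability vector p is converted to survivor values by tail
    sums, S1(t) = sum of p over intervals entirely beyond t, which makes
    every draw nonincreasing over the nodes by construction.  t0 is merged
    into the partition so S1(t0) is an exact tail sum.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    rng = as_generator(rng_seed)
    partition = build_partition(grid, data, extra_cuts=(t0,))
    alphas = prior.alphas(partition)
    node_pos = np.array([partition.cut_index(u) for u in grid.nodes])
    t0_pos = partition.cut_index(t0)

    p = alphas / alphas.sum()
    n_keep = n_iter - burn_in
    node_samples = np.empty((n_keep, grid.n_nodes))
    t0_samples = np.empty(n_keep)
    for it in range(n_iter):
        _, d_prime = gibbs_impute_censored(p, partition, rng)
        p = gibbs_update_p(d_prime, alphas, rng)
        if it >= burn_in:
            surv = 1.0 - np.cumsum(p)[:-1]  # survivor at each cut point
            surv = np.clip(surv, 0.0, 1.0)
            j = it - burn_in
            node_samples[j] = surv[node_pos]
            t0_samples[j] = surv[t0_pos]
    return SurvivorDraws(
        nodes=grid.nodes,
        node_samples=node_samples,
        t0=t0,
        t0_samples=t0_samples,
        seed=rng_seed if isinstance(rng_seed, int) else None,
        burn_in=burn_in,
    )
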