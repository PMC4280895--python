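"""Logrank power and assurance under proportional hazards with uniform entry.

The analysis is a two-sided logrank test of H0: theta = 0, where
theta = log(phi) and phi = h2(t)/h1(t) is the (constant) hazard ratio.  With
total sample size N, allocation proportions Q1, Q2 and overall event
probability Pe, the asymptotic power is

    pi = Phi( |theta| * sqrt(N * Pe * Q1 * Q2) - z_{1-alpha/2} ),

i.e. power depends on the design only through the expected number of events
d = N * Pe.  Pe is obtained from the control survivor function by averaging
over uniform entry times:

    P1e = 1 - (1/R) * int_{T-R}^{T} S1(u) du,
    P2e = 1 - (1/R) * int_{T-R}^{T} S1(u)**exp(theta) du,

with the integrals evaluated by composite Simpson quadrature on an odd number
of equally spaced nodes.  The log hazard ratio is tied to survival rates at
an anchor time t0 via  theta = ln( ln(S1(t0) + rho) / ln(S1(t0)) ),  where
rho is the survival-rate difference (experimental minus control).

Two assurance routines cover the cases with and without historical control
data: without data, the control curve inside the P2e identity is taken to be
exponential through the sampled P1e; with data, posterior draws of the
control survivor function (see :mod:`survassure.dp_posterior`) are consumed
directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from ._rng import as_generator
from .design import AssuranceResult, TrialDesign
from .exponential import event_prob_exponential
from .priors import PriorSpec, _truncated_ppf_draws, sample_prior

__all__ = [
    "QuadratureGrid",
    "simpson_integral",
    "theta_from_rates",
    "event_probabilities",
    "power_logrank",
    "success_prob_logrank",
    "implied_rate_from_event_prob",
    "assurance_ph_no_data",
    "assurance_ph_with_data",
    "assurance_ph_normal_theta",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced Simpson nodes on [lower, upper] with weights 1,4,2,...,4,1."""

    lower: float
    upper: float
    n_nodes: int = 11

    def __post_init__(self):
        if self.n_nodes < 3 or self.n_nodes % 2 == 0:
            raise ValueError("Simpson's rule needs an odd number of nodes >= 3")
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")

    @classmethod
    def for_design(cls, design: TrialDesign, n_nodes: int = 11) -> "QuadratureGrid":
        """Nodes on [T - R, T], the window of possible censoring times."""
        return cls(design.T - design.R, design.T, n_nodes)

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_nodes)

    @property
    def weights(self) -> np.ndarray:
        w = np.ones(self.n_nodes)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        return w

    @property
    def step(self) -> float:
        return (self.upper - self.lower) / (self.n_nodes - 1)


def simpson_integral(values, grid: QuadratureGrid):
    """Composite Simpson estimate of the integral of f over [lower, upper]
    given f at the grid nodes.  ``values`` may be (n_nodes,) or
    (m, n_nodes) for m integrands at once."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != grid.n_nodes:
        raise ValueError("values must be evaluated at every grid node")
    out = (grid.step / 3.0) * values @ grid.weights
    return float(out) if np.ndim(out) == 0 else out


def theta_from_rates(s1_t0, rho):
    """Log hazard ratio implied by the survival rates at t0:
    theta = ln( ln(s1 + rho) / ln(s1) ); negative exactly when rho > 0."""
    s1 = np.asarray(s1_t0, dtype=float)
    rho = np.asarray(rho, dtype=float)
    s2 = s1 + rho
    if np.any(s1 <= 0) or np.any(s1 >= 1) or np.any(s2 <= 0) or np.any(s2 >= 1):
        raise ValueError("both survival rates must lie strictly in (0,1)")
    out = np.log(np.log(s2) / np.log(s1))
    return float(out) if out.ndim == 0 else out


def event_probabilities(s1_values, theta, design: TrialDesign, grid: QuadratureGrid):
    """Per-group and pooled event probabilities from the control survivor
    function evaluated at the grid nodes.

    ``s1_values`` may be (n_nodes,) with scalar theta, or (m, n_nodes) with
    theta of length m.  Quadrature on step functions can overshoot slightly;
    results are clipped to [0,1] with a warning.
    """
    s1_values = np.asarray(s1_values, dtype=float)
    if np.any(s1_values < 0) or np.any(s1_values > 1):
        raise ValueError("survivor values must lie in [0,1]")
    theta = np.asarray(theta, dtype=float)
    R = design.R
    if not math.isclose(grid.upper - grid.lower, R, rel_tol=1e-9):
        raise ValueError("quadrature grid must span an interval of length R")
    p1 = 1.0 - simpson_integral(s1_values, grid) / R
    hr = np.exp(theta)
    if s1_values.ndim == 2:
        s2_values = s1_values ** hr[:, None]
    else:
        s2_values = s1_values**hr
    p2 = 1.0 - simpson_integral(s2_values, grid) / R
    stacked = np.stack([np.atleast_1d(p1), np.atleast_1d(p2)])
    if np.any(stacked < -1e-9) or np.any(stacked > 1 + 1e-9):
        warnings.warn("Simpson quadrature over/undershoot on a step survivor; clipping to [0,1]")
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    pe = design.q1 * p1 + design.q2 * p2
    if np.ndim(pe) == 0:
        return float(p1), float(p2), float(pe)
    return p1, p2, pe


def power_logrank(n_total, theta, pe, design: TrialDesign):
    """Schoenfeld asymptotic power of the two-sided logrank test."""
    theta = np.asarray(theta, dtype=float)
    pe = np.asarray(pe, dtype=float)
    z = stats.norm.ppf(1.0 - design.alpha / 2.0)
    arg = np.abs(theta) * np.sqrt(n_total * pe * design.q1 * design.q2) - z
    out = stats.norm.cdf(arg)
    return float(out) if np.ndim(out) == 0 else out


def success_prob_logrank(n_total, theta, pe, design: TrialDesign):
    """One-sided probability of rejection with the experimental hazard
    estimated lower (the success direction)."""
    theta = np.asarray(theta, dtype=float)
    pe = np.asarray(pe, dtype=float)
    z = stats.norm.ppf(1.0 - design.alpha / 2.0)
    out = stats.norm.cdf(-theta * np.sqrt(n_total * pe * design.q1 * design.q2) - z)
    return float(out) if np.ndim(out) == 0 else out


def implied_rate_from_event_prob(p1e: float, design: TrialDesign) -> float:
    """Exponential hazard rate whose uniform-entry event probability equals
    ``p1e`` (monotone in the rate, solved by bracketing)."""
    if not 0 < p1e < 1:
        raise ValueError("event probability must lie strictly in (0,1)")

    def f(log_lam):
        return event_prob_exponential(math.exp(log_lam), design) - p1e

    lo, hi = -30.0, 10.0
    while f(hi) < 0 and hi < 40:
        hi += 10.0
    return math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))


def _ph_result(success_probs, rho, seed, model="ph") -> AssuranceResult:
    m = len(success_probs)
    gamma = float(np.mean(success_probs))
    se = math.sqrt(max(gamma * (1.0 - gamma), 0.0) / m)
    return AssuranceResult(
        estimate=gamma,
        se=se,
        n_draws=m,
        seed=seed if isinstance(seed, int) else None,
        prior_superiority=float(np.mean(np.asarray(rho) > 0)),
        model=model,
    )


def assurance_ph_no_data(
    p1e_prior: PriorSpec,
    s1t0_prior: PriorSpec,
    rho_prior: PriorSpec,
    design: TrialDesign,
    M: int = 10_000,
    rng_seed=None,
) -> AssuranceResult:
    """Assurance under proportional hazards with no historical control data.

    Beliefs are elicited directly about the control event probability P1e,
    the control survival rate S1(t0) and the survival difference rho
    (independent priors; rho truncated per draw so S1(t0) + rho stays in
    (0,1)).  P2e needs a curve shape: the control survivor is taken to be
    exponential through the sampled P1e, under which
    P2e = event_prob_exponential(rate * hazard-ratio).
    """
    rng = as_generator(rng_seed)
    p1e = sample_prior(p1e_prior, M, rng)
    if np.any(p1e <= 0) or np.any(p1e >= 1):
        raise ValueError("P1e prior must be supported on (0,1)")
    s1 = sample_prior(s1t0_prior, M, rng)
    lower = -s1
    upper = 1.0 - s1
    if rho_prior.is_point:
        rho = np.full(M, rho_prior.params[0])
        if np.any(rho <= lower) or np.any(rho >= upper):
            raise ValueError("point survival difference leaves S2 outside (0,1)")
    else:
        if rho_prior.lower is not None:
            lower = np.maximum(lower, rho_prior.lower)
        if rho_prior.upper is not None:
            upper = np.minimum(upper, rho_prior.upper)
        rho = _truncated_ppf_draws(rho_prior.distribution(), lower, upper, M, rng)
    theta = theta_from_rates(s1, rho)
    rates = np.array([implied_rate_from_event_prob(p, design) for p in np.atleast_1d(p1e)])
    p2e = event_prob_exponential(rates * np.exp(theta), design)
    pe = design.q1 * p1e + design.q2 * p2e
    probs = success_prob_logrank(design.n_total, theta, pe, design)
    return _ph_result(np.atleast_1d(probs), rho, rng_seed)


def assurance_ph_with_data(
    survivor_draws,
    rho_prior: PriorSpec,
    design: TrialDesign,
    grid: QuadratureGrid,
    M: Optional[int] = None,
    rng_seed=None,
) -> AssuranceResult:
    """Assurance under proportional hazards using posterior draws of the
    control survivor function (e.g. from the Dirichlet-process Gibbs
    sampler).

    Each Monte Carlo iteration pairs one survivor draw (values at the
    quadrature nodes plus at the anchor time t0) with a draw of the survival
    difference rho, truncated so S1(t0) + rho stays in (0,1).  If ``M``
    exceeds the number of stored draws they are recycled in a reshuffled
    order.
    """
    rng = as_generator(rng_seed)
    nodes_matrix = np.asarray(survivor_draws.node_samples, dtype=float)
    s1t0 = np.asarray(survivor_draws.t0_samples, dtype=float)
    if nodes_matrix.shape[1] != grid.n_nodes or not np.allclose(
        survivor_draws.nodes, grid.nodes, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("survivor draws were generated on a different quadrature grid")
    n_avail = nodes_matrix.shape[0]
    if M is None or M == n_avail:
        idx = np.arange(n_avail)
    else:
        idx = rng.permutation(n_avail)
        if M > n_avail:
            idx = np.concatenate([idx, rng.integers(0, n_avail, M - n_avail)])
        idx = idx[:M]
    s1_nodes = nodes_matrix[idx]
    s1t0 = np.clip(s1t0[idx], 1e-12, 1 - 1e-12)

    lower = -s1t0
    upper = 1.0 - s1t0
    if rho_prior.is_point:
        rho = np.full(len(idx), rho_prior.params[0])
        if np.any(rho <= lower) or np.any(rho >= upper):
            raise ValueError("point survival difference leaves S2 outside (0,1)")
    else:
        if rho_prior.lower is not None:
            lower = np.maximum(lower, rho_prior.lower)
        if rho_prior.upper is not None:
            upper = np.minimum(upper, rho_prior.upper)
        rho = _truncated_ppf_draws(rho_prior.distribution(), lower, upper, len(idx), rng)
    theta = theta_from_rates(s1t0, rho)
    # quadrature needs survivor values strictly handled; clip guards exact 0/1
    s1_nodes = np.clip(s1_nodes, 0.0, 1.0)
    _, _, pe = event_probabilities(s1_nodes, theta, design, grid)
    probs = success_prob_logrank(design.n_total, theta, pe, design)
    return _ph_result(np.atleast_1d(probs), rho, rng_seed)


def assurance_ph_normal_theta(
    mean: float,
    variance: float,
    pe: float,
    design: TrialDesign,
    method: str = "quadrature",
    M: int = 1_000_000,
    rng_seed=None,
    n_quad: int = 60,
) -> float:
    """Assurance with a normal prior on the log hazard ratio and fixed Pe.

    With only theta uncertain the assurance is a one-dimensional integral of
    the success probability against the normal prior; ``method="quadrature"``
    evaluates it by Gauss–Hermite quadrature, ``method="mc"`` by plain Monte
    Carlo.  The two agree to Monte Carlo accuracy, which the test suite uses
    as a consistency check on the assurance integrand.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    if method == "quadrature":
        x, w = np.polynomial.hermite_e.hermegauss(n_quad)
        theta = mean + math.sqrt(variance) * x
        probs = success_prob_logrank(design.n_total, theta, pe, design)
        return float(np.sum(w * probs) / math.sqrt(2.0 * math.pi))
    if method == "mc":
        rng = as_generator(rng_seed)
        theta = rng.normal(mean, math.sqrt(variance), M)
        return float(np.mean(success_prob_logrank(design.n_total, theta, pe, design)))
    raise ValueError("method must be 'quadrature' or 'mc'")
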