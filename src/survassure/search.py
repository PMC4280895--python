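"""Sample-size search and power/assurance curves over per-group sample size.

Assurance curves reuse one set of prior draws across every sample size
(common random numbers), so the Monte Carlo noise is shared across the curve
and the monotone trend is not obscured by independent jitter.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

from ._rng import as_generator
from .design import Curve, TrialDesign
from . import exponential as expo
from . import prop_hazards as ph
from . import weibull as wb
from .priors import joint_rates_sample

__all__ = ["sample_size_for_power", "assurance_curve"]


def sample_size_for_power(
    power_fn: Callable[[int], float],
    target: float,
    n_min: int = 1,
    n_max: int = 10_000_000,
) -> int:
    """Smallest integer per-group sample size with ``power_fn(n) >= target``.

    ``power_fn`` must be nondecreasing in n over [n_min, n_max]; the search
    brackets by doubling and finishes by integer bisection.
    """
    if not 0 < target < 1:
        raise ValueError("target power must lie in (0,1)")
    if power_fn(n_min) >= target:
        return n_min
    lo, hi = n_min, max(2 * n_min, 2)
    while power_fn(hi) < target:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power {target} not reachable with n <= {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_fn(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def _mc_se(gamma: float, m: int) -> float:
    return math.sqrt(max(gamma * (1.0 - gamma), 0.0) / m)


def assurance_curve(
    model: str,
    priors,
    design: TrialDesign,
    n_grid: Sequence[int],
    M: int = 10_000,
    rng_seed=None,
    power_params=None,
) -> Curve:
    """Assurance (and optionally power) as a function of per-group size.

    ``model`` selects the survival model and fixes what ``priors`` and
    ``power_params`` contain:

    * ``"exponential"`` — priors ``(s1_prior, rho_prior, t0)``;
      power_params ``(lambda1, lambda2)``.
    * ``"weibull"`` — priors a :class:`~survassure.weibull.WeibullPriors`;
      power_params ``(kappa1, lam1, kappa2, lam2)``.
    * ``"ph"`` — priors ``(survivor_draws, rho_prior, grid)``;
      power_params ``(theta, pe)``.
    * ``"ph_no_data"`` — priors ``(p1e_prior, s1t0_prior, rho_prior)``;
      power_params ``(theta, pe)``.

    The power column uses the fixed design-stage parameter values in
    ``power_params`` (omitted if None).
    """
    n_grid = np.asarray(list(n_grid), dtype=int)
    if np.any(n_grid < 1):
        raise ValueError("sample sizes must be positive integers")
    rng = as_generator(rng_seed)

    if model == "exponential":
        s1_prior, rho_prior, t0 = priors
        s1, s2 = joint_rates_sample(s1_prior, rho_prior, M, rng)
        l1 = expo.lambda_from_survival(s1, t0)
        l2 = expo.lambda_from_survival(s2, t0)
        assurance = np.array(
            [np.mean(expo.success_prob_exponential(l1, l2, design.with_per_group(n))) for n in n_grid]
        )
        power = (
            None
            if power_params is None
            else np.array([expo.power_exponential(*power_params, design.with_per_group(n)) for n in n_grid])
        )
    elif model == "weibull":
        s1a, s1b, s2a, s2b = wb.rates_from_deltas(priors, M, rng)
        k1, l1 = wb.weibull_from_two_rates(s1a, s1b, priors.t0, priors.t0p)
        k2, l2 = wb.weibull_from_two_rates(s2a, s2b, priors.t0, priors.t0p)
        assurance = np.empty(len(n_grid))
        for i, n in enumerate(n_grid):
            d = design.with_per_group(int(n))
            success = np.empty(M, dtype=bool)
            for start in range(0, M, 200):
                sl = slice(start, min(start + 200, M))
                m = sl.stop - sl.start
                x1 = wb.sample_weibull_times(k1[sl][:, None], l1[sl][:, None], (m, d.n1), rng)
                x2 = wb.sample_weibull_times(k2[sl][:, None], l2[sl][:, None], (m, d.n2), rng)
                success[sl] = wb._welch_success(x1, x2, d.alpha)
            assurance[i] = success.mean()
        power = (
            None
            if power_params is None
            else np.array([wb.power_weibull(*power_params, design.with_per_group(int(n))) for n in n_grid])
        )
    elif model in ("ph", "ph_no_data"):
        if model == "ph":
            draws, rho_prior, grid = priors
            theta, pe = _ph_draws(draws, rho_prior, design, grid, M, rng)
        else:
            p1e_prior, s1t0_prior, rho_prior = priors
            theta, pe = _ph_no_data_draws(p1e_prior, s1t0_prior, rho_prior, design, M, rng)
        assurance = np.array(
            [
                np.mean(ph.success_prob_logrank(design.with_per_group(int(n)).n_total, theta, pe, design))
                for n in n_grid
            ]
        )
        power = (
            None
            if power_params is None
            else np.array(
                [
                    ph.power_logrank(design.with_per_group(int(n)).n_total, power_params[0], power_params[1], design)
                    for n in n_grid
                ]
            )
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    se = np.array([_mc_se(g, M) for g in assurance])
    return Curve(n=n_grid, assurance=assurance, assurance_se=se, power=power, model=model)


def _ph_draws(draws, rho_prior, design, grid, M, rng):
    """Shared (theta, Pe) draws for a curve: pair survivor draws with rho
    draws once, so every point on the n grid uses the same randomness."""
    nodes_matrix = np.asarray(draws.node_samples, dtype=float)
    s1t0 = np.clip(np.asarray(draws.t0_samples, dtype=float), 1e-12, 1 - 1e-12)
    n_avail = nodes_matrix.shape[0]
    idx = rng.permutation(n_avail)
    if M > n_avail:
        idx = np.concatenate([idx, rng.integers(0, n_avail, M - n_avail)])
    idx = idx[:M]
    s1_nodes = np.clip(nodes_matrix[idx], 0.0, 1.0)
    s1t0 = s1t0[idx]
    lower, upper = -s1t0, 1.0 - s1t0
    if rho_prior.is_point:
        rho = np.full(len(idx), rho_prior.params[0])
    else:
        if rho_prior.lower is not None:
            lower = np.maximum(lower, rho_prior.lower)
        if rho_prior.upper is not None:
            upper = np.minimum(upper, rho_prior.upper)
        from .priors import _truncated_ppf_draws

        rho = _truncated_ppf_draws(rho_prior.distribution(), lower, upper, len(idx), rng)
    theta = ph.theta_from_rates(s1t0, rho)
    _, _, pe = ph.event_probabilities(s1_nodes, theta, design, grid)
    return theta, pe


def _ph_no_data_draws(p1e_prior, s1t0_prior, rho_prior, design, M, rng):
    from .priors import _truncated_ppf_draws, sample_prior

    p1e = sample_prior(p1e_prior, M, rng)
    s1 = sample_prior(s1t0_prior, M, rng)
    lower, upper = -s1, 1.0 - s1
    if rho_prior.is_point:
        rho = np.full(M, rho_prior.params[0])
    else:
        if rho_prior.lower is not None:
            lower = np.maximum(lower, rho_prior.lower)
        if rho_prior.upper is not None:
            upper = np.minimum(upper, rho_prior.upper)
        rho = _truncated_ppf_draws(rho_prior.distribution(), lower, upper, M, rng)
    theta = ph.theta_from_rates(s1, rho)
    rates = np.array([ph.implied_rate_from_event_prob(p, design) for p in np.atleast_1d(p1e)])
    p2e = expo.event_prob_exponential(rates * np.exp(theta), design)
    pe = design.q1 * p1e + design.q2 * p2e
    return theta, pe
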