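"""Power and assurance for Weibull survival analysed via mean survival times.

Survivor function convention: S(t) = exp(-lam * t**kappa) with shape kappa
and scale lam (so kappa = 1 is the exponential with rate lam).  The planned
analysis compares mean survival times.  Under this analysis every survival
time is observed in full, so the recruitment and follow-up lengths play no
role in this model: the design only contributes the group sizes and the test
level.

The design-stage power treats the variances as known (normal approximation to
the sample means); the assurance Monte Carlo instead simulates each candidate
trial outright and applies Welch's unequal-variance t-test, because at
analysis time the variances would be estimated.

Shape and scale are recovered from survival rates at two anchor times
t0 < t0p:

    kappa = ln( ln(S_b) / ln(S_a) ) / ln(t0p / t0),
    lam   = -ln(S_a) / t0**kappa,

with S_a = S(t0), S_b = S(t0p).  Priors on the four rates are induced from
priors on S1(t0) and three survival-rate differences (or odds ratios), each
truncated so that both survivor curves stay inside (0,1) and decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ._rng import as_generator
from .design import AssuranceResult, TrialDesign
from .priors import PriorSpec, _truncated_ppf_draws, sample_prior

__all__ = [
    "WeibullPriors",
    "weibull_from_two_rates",
    "weibull_survivor",
    "weibull_moments",
    "sample_weibull_times",
    "power_weibull",
    "rates_from_deltas",
    "assurance_weibull",
]

_MIN_SHAPE = 1e-3


def weibull_from_two_rates(s_a, s_b, t0: float, t0p: float):
    """Recover (shape, scale) from survival rates at two times.

    Requires 0 < s_b < s_a < 1 (the survivor function decreases) and
    0 < t0 < t0p.  Round-trips with :func:`weibull_survivor` to ~1e-10.
    """
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if not 0 < t0 < t0p:
        raise ValueError("anchor times must satisfy 0 < t0 < t0p")
    if np.any(s_a <= 0) or np.any(s_a >= 1) or np.any(s_b <= 0) or np.any(s_b >= 1):
        raise ValueError("survival rates must lie strictly in (0,1)")
    if np.any(s_b >= s_a):
        raise ValueError("survivor must decrease: need s_b < s_a")
    kappa = np.log(np.log(s_b) / np.log(s_a)) / math.log(t0p / t0)
    lam = -np.log(s_a) / t0**kappa
    if np.ndim(kappa) == 0:
        return float(kappa), float(lam)
    return kappa, lam


def weibull_survivor(t, kappa, lam):
    """S(t) = exp(-lam * t**kappa)."""
    return np.exp(-np.asarray(lam) * np.asarray(t) ** np.asarray(kappa))


def weibull_moments(kappa, lam):
    """Mean and variance of the survival time:

    mu  = lam**(-1/kappa) * Gamma(1 + 1/kappa)
    var = lam**(-2/kappa) * (Gamma(1 + 2/kappa) - Gamma(1 + 1/kappa)**2)
    """
    kappa = np.asarray(kappa, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(kappa < _MIN_SHAPE):
        raise ValueError(f"shape below {_MIN_SHAPE} overflows the moment formulas")
    if np.any(lam <= 0):
        raise ValueError("scale must be positive")
    # log-space evaluation: small shapes make Gamma(1 + 2/kappa) astronomically
    # large, so the naive product overflows long before the result does
    g1l = gammaln(1.0 + 1.0 / kappa)
    g2l = gammaln(1.0 + 2.0 / kappa)
    log_mu = -np.log(lam) / kappa + g1l
    log_var = -2.0 * np.log(lam) / kappa + g2l + np.log1p(-np.exp(2.0 * g1l - g2l))
    with np.errstate(over="ignore"):
        mu = np.exp(log_mu)
        var = np.exp(log_var)
    if np.ndim(mu) == 0:
        return float(mu), float(var)
    return mu, var


def weibull_log_mean(kappa, lam):
    """log of the mean survival time; finite even where the mean overflows."""
    kappa = np.asarray(kappa, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return -np.log(lam) / kappa + gammaln(1.0 + 1.0 / kappa)


def sample_weibull_times(kappa, lam, size, rng_seed=None) -> np.ndarray:
    """Simulate survival times; kappa/lam broadcast against ``size``."""
    rng = as_generator(rng_seed)
    return rng.weibull(np.asarray(kappa), size) * np.asarray(lam) ** (-1.0 / np.asarray(kappa))


def power_weibull(kappa1, lam1, kappa2, lam2, design: TrialDesign):
    """Normal-approximation power of the two-sided test of equal mean survival
    with known variances."""
    mu1, v1 = weibull_moments(kappa1, lam1)
    mu2, v2 = weibull_moments(kappa2, lam2)
    se = np.sqrt(v1 / design.n1 + v2 / design.n2)
    z = stats.norm.ppf(1.0 - design.alpha / 2.0)
    out = stats.norm.cdf(np.abs(mu2 - mu1) / se - z)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class WeibullPriors:
    """Elicited priors inducing a joint prior on both groups' Weibull
    parameters.

    With the default difference parameterisation the components are:

    * ``s1_prior`` — prior for S1(t0), supported on (0,1);
    * ``d11_prior`` — prior for S1(t0) - S1(t0p) (control drop, in (0,1));
    * ``d12_prior`` — prior for S2(t0) - S1(t0) (between-group difference);
    * ``d22_prior`` — prior for S2(t0) - S2(t0p) (experimental drop).

    With ``odds_ratio=True`` the three component priors are instead for the
    odds ratios odds(S1(t0p))/odds(S1(t0)), odds(S2(t0))/odds(S1(t0)) and
    odds(S2(t0p))/odds(S2(t0)) (typically lognormal); the within-group odds
    ratios are truncated below 1 so each survivor curve decreases.
    """

    s1_prior: PriorSpec
    d11_prior: PriorSpec
    d12_prior: PriorSpec
    d22_prior: PriorSpec
    t0: float
    t0p: float
    odds_ratio: bool = False

    def __post_init__(self):
        if not 0 < self.t0 < self.t0p:
            raise ValueError("anchor times must satisfy 0 < t0 < t0p")
        lo, hi = self.s1_prior.support()
        if lo < 0 or hi > 1:
            raise ValueError("S1(t0) prior must be supported on (0,1)")


def _draw_truncated(prior: PriorSpec, lower, upper, n, rng) -> np.ndarray:
    """Per-draw truncation of a component prior to array bounds."""
    if prior.lower is not None:
        lower = np.maximum(lower, prior.lower)
    if prior.upper is not None:
        upper = np.minimum(upper, prior.upper)
    if prior.is_point:
        v = prior.params[0]
        if np.any(v <= lower) or np.any(v >= upper):
            raise ValueError("point prior value violates the feasibility bounds")
        return np.full(n, v)
    return _truncated_ppf_draws(prior.distribution(), lower, upper, n, rng)


def rates_from_deltas(priors: WeibullPriors, n: int, rng_seed=None) -> tuple:
    """Sample the four survival rates (S1(t0), S1(t0p), S2(t0), S2(t0p)).

    The components are drawn sequentially — S1(t0), then the control drop,
    the between-group difference and the experimental drop — each truncated
    to whatever range keeps all four rates in (0,1) with both survivor
    curves decreasing.
    """
    rng = as_generator(rng_seed)
    s1a = sample_prior(priors.s1_prior, n, rng)
    if priors.odds_ratio:
        odds1a = s1a / (1.0 - s1a)
        o11 = _draw_truncated(priors.d11_prior, np.zeros(n), np.ones(n), n, rng)
        s1b = (odds1a * o11) / (1.0 + odds1a * o11)
        o12 = _draw_truncated(priors.d12_prior, np.zeros(n), np.full(n, np.inf), n, rng)
        s2a = (odds1a * o12) / (1.0 + odds1a * o12)
        odds2a = s2a / (1.0 - s2a)
        o22 = _draw_truncated(priors.d22_prior, np.zeros(n), np.ones(n), n, rng)
        s2b = (odds2a * o22) / (1.0 + odds2a * o22)
    else:
        d11 = _draw_truncated(priors.d11_prior, np.zeros(n), s1a, n, rng)
        s1b = s1a - d11
        d12 = _draw_truncated(priors.d12_prior, -s1a, 1.0 - s1a, n, rng)
        s2a = s1a + d12
        d22 = _draw_truncated(priors.d22_prior, np.zeros(n), s2a, n, rng)
        s2b = s2a - d22
    return s1a, s1b, s2a, s2b


def assurance_weibull(
    priors: WeibullPriors,
    design: TrialDesign,
    M: int = 2_000,
    rng_seed=None,
    _batch: int = 200,
) -> AssuranceResult:
    """Monte Carlo assurance under the Weibull model.

    Each iteration samples the four survival rates, converts them to Weibull
    parameters, simulates a complete trial (n1 + n2 fully observed survival
    times) and applies Welch's t-test; success is rejection with the
    experimental sample mean larger.  The estimate is the success fraction.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if design.n1 < 2 or design.n2 < 2:
        raise ValueError("need at least 2 patients per group for a t-test")
    rng = as_generator(rng_seed)
    s1a, s1b, s2a, s2b = rates_from_deltas(priors, M, rng)
    k1, l1 = weibull_from_two_rates(s1a, s1b, priors.t0, priors.t0p)
    k2, l2 = weibull_from_two_rates(s2a, s2b, priors.t0, priors.t0p)
    log_mu1 = weibull_log_mean(k1, l1)
    log_mu2 = weibull_log_mean(k2, l2)

    success = np.empty(M, dtype=bool)
    for start in range(0, M, _batch):
        sl = slice(start, min(start + _batch, M))
        m = sl.stop - sl.start
        x1 = sample_weibull_times(k1[sl][:, None], l1[sl][:, None], (m, design.n1), rng)
        x2 = sample_weibull_times(k2[sl][:, None], l2[sl][:, None], (m, design.n2), rng)
        success[sl] = _welch_success(x1, x2, design.alpha)

    gamma = float(success.mean())
    se = math.sqrt(gamma * (1.0 - gamma) / M)
    return AssuranceResult(
        estimate=gamma,
        se=se,
        n_draws=M,
        seed=rng_seed if isinstance(rng_seed, int) else None,
        prior_superiority=float(np.mean(log_mu2 > log_mu1)),
        model="weibull",
    )


def _welch_success(x1: np.ndarray, x2: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised Welch t-test over trials in rows; success = reject with
    mean2 > mean1."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    a = v1 / n1
    b = v2 / n2
    se2 = a + b
    t = (m2 - m1) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom in a scale-invariant form so
    # heavy-tailed draws (huge variances) cannot overflow the intermediates
    fa = a / se2
    fb = b / se2
    nu = 1.0 / (fa**2 / (n1 - 1) + fb**2 / (n2 - 1))
    crit = stats.t.ppf(1.0 - alpha / 2.0, nu)
    return t > crit
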