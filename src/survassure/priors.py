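"""Prior elicitation: turn expert judgements into parametric priors.

Two judgement formats are supported:

* **trial roulette** — the expert distributes chips over equal-width bins;
  chips / total chips is read as the probability of each bin;
* **quartiles** — the expert states the lower quartile, median and upper
  quartile of the uncertain quantity.

A parametric family (beta, normal, lognormal or a degenerate point mass) is
fitted by least squares on the probability scale: the parameters minimise the
sum of squared differences between the elicited probabilities and the
probabilities implied by the fitted CDF.  The same objective is used for both
formats so that feedback to the expert is comparable.

Sampling from a fitted prior supports truncation to an interval, implemented
by inverse-CDF sampling on the renormalised range (never by clipping), so
truncated draws follow the renormalised density exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from ._rng import as_generator

__all__ = [
    "PriorSpec",
    "RouletteJudgement",
    "QuartileJudgement",
    "PriorFit",
    "fit_to_roulette",
    "fit_to_quartiles",
    "sample_prior",
    "joint_rates_sample",
]

FAMILIES = ("beta", "normal", "lognormal", "point")


@dataclass(frozen=True)
class PriorSpec:
    """A univariate elicited prior.

    Parameters
    ----------
    family
        One of ``"beta"`` (params ``(a, b)``), ``"normal"`` (params
        ``(mean, variance)``), ``"lognormal"`` (params
        ``(log_mean, log_variance)``) or ``"point"`` (params ``(value,)``).
    params
        Family-specific parameters, see above.  Normal and lognormal are
        parameterised by a *variance*, not a standard deviation, matching the
        way elicited priors are usually reported.
    lower, upper
        Optional truncation bounds; sampling renormalises the density to
        ``(lower, upper)``.
    """

    family: str
    params: tuple
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError("beta prior requires shape parameters a > 0, b > 0")
        elif self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("normal prior requires (mean, variance) with variance > 0")
        elif self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError("lognormal prior requires (log-mean, log-variance) with log-variance > 0")
        elif self.family == "point":
            if len(p) != 1:
                raise ValueError("point prior takes a single value")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError("truncation bounds require lower < upper")
        if self.family != "point" and (self.lower is not None or self.upper is not None):
            lo = -np.inf if self.lower is None else self.lower
            hi = np.inf if self.upper is None else self.upper
            d = self.distribution()
            if d.cdf(hi) - d.cdf(lo) <= 0.0:
                raise ValueError("untruncated distribution places no mass inside the truncation bounds")

    # -- distribution plumbing -------------------------------------------------
    def distribution(self):
        """Frozen scipy distribution of the *untruncated* prior (None for point)."""
        p = self.params
        if self.family == "beta":
            return stats.beta(p[0], p[1])
        if self.family == "normal":
            return stats.norm(loc=p[0], scale=math.sqrt(p[1]))
        if self.family == "lognormal":
            return stats.lognorm(s=math.sqrt(p[1]), scale=math.exp(p[0]))
        return None

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def support(self) -> tuple:
        if self.family == "beta":
            base = (0.0, 1.0)
        elif self.family == "lognormal":
            base = (0.0, np.inf)
        elif self.family == "point":
            return (self.params[0], self.params[0])
        else:
            base = (-np.inf, np.inf)
        lo = base[0] if self.lower is None else max(base[0], self.lower)
        hi = base[1] if self.upper is None else min(base[1], self.upper)
        return (lo, hi)

    def mean(self) -> float:
        """Mean of the (possibly truncated) prior, by quadrature when truncated."""
        if self.is_point:
            return self.params[0]
        d = self.distribution()
        if self.lower is None and self.upper is None:
            return float(d.mean())
        lo, hi = self.support()
        # mean of the renormalised density via the inverse-CDF representation
        a, b = d.cdf(lo), d.cdf(hi)
        from scipy.integrate import quad

        val, _ = quad(lambda u: d.ppf(a + (b - a) * u), 0.0, 1.0, limit=200)
        return float(val)

    def truncated(self, lower=None, upper=None) -> "PriorSpec":
        """Copy of this spec with tightened truncation bounds."""
        lo = self.lower if lower is None else (lower if self.lower is None else max(lower, self.lower))
        hi = self.upper if upper is None else (upper if self.upper is None else min(upper, self.upper))
        return replace(self, lower=lo, upper=hi)

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        out = {"family": self.family, "params": list(self.params)}
        if self.lower is not None:
            out["lower"] = self.lower
        if self.upper is not None:
            out["upper"] = self.upper
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(d["family"], tuple(d["params"]), d.get("lower"), d.get("upper"))


@dataclass(frozen=True)
class RouletteJudgement:
    """Chips allocated to equal-width bins on a plausible range."""

    bin_edges: np.ndarray
    chips: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        chips = np.asarray(self.chips)
        if np.any(chips < 0) or not np.allclose(chips, np.round(chips)):
            raise ValueError("chips must be non-negative integers")
        chips = chips.astype(int)
        if edges.ndim != 1 or len(edges) != len(chips) + 1:
            raise ValueError("need one more bin edge than bins")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bins must have equal width")
        if chips.sum() <= 0:
            raise ValueError("at least one chip is required")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "chips", chips)

    @classmethod
    def from_range(cls, lower: float, upper: float, chips: Sequence[int]) -> "RouletteJudgement":
        """Equal-width bins spanning ``(lower, upper)``, the usual roulette layout."""
        edges = np.linspace(lower, upper, len(chips) + 1)
        return cls(edges, np.asarray(chips))

    @property
    def total_chips(self) -> int:
        return int(self.chips.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.chips / self.total_chips


@dataclass(frozen=True)
class QuartileJudgement:
    q25: float
    q50: float
    q75: float

    def __post_init__(self):
        if not self.q25 < self.q50 < self.q75:
            raise ValueError("quartiles must satisfy q25 < q50 < q75")


@dataclass(frozen=True)
class PriorFit:
    """A fitted prior plus the achieved sum of squares, for expert feedback."""

    prior: PriorSpec
    ssq: float


# ---------------------------------------------------------------------------
# least-squares fitting
# ---------------------------------------------------------------------------

_Z75 = stats.norm.ppf(0.75)  # 0.6745


def _spec_from_vector(family: str, x: np.ndarray) -> PriorSpec:
    if family == "beta":
        return PriorSpec("beta", (math.exp(x[0]), math.exp(x[1])))
    if family == "normal":
        return PriorSpec("normal", (x[0], math.exp(2.0 * x[1])))
    if family == "lognormal":
        return PriorSpec("lognormal", (x[0], math.exp(2.0 * x[1])))
    raise ValueError(f"cannot fit family {family!r}")


def _initial_vectors(family: str, mean: float, sd: float) -> list:
    """Moment-matched start plus perturbations (beta SSQ surfaces can be flat)."""
    sd = max(sd, 1e-6)
    inits = []
    if family == "beta":
        m = min(max(mean, 1e-3), 1 - 1e-3)
        v = min(sd**2, m * (1 - m) * 0.999)
        conc = m * (1 - m) / v - 1.0
        conc = max(conc, 0.1)
        inits.append([math.log(m * conc), math.log((1 - m) * conc)])
        inits.append([math.log(max(m * conc * 3, 0.2)), math.log(max((1 - m) * conc * 3, 0.2))])
        inits.append([0.0, 0.0])
    elif family == "normal":
        inits.append([mean, math.log(sd)])
        inits.append([mean, math.log(sd * 2)])
    elif family == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal family requires positive support")
        cv2 = (sd / mean) ** 2
        lv = math.log1p(cv2)
        inits.append([math.log(mean) - lv / 2, 0.5 * math.log(max(lv, 1e-8))])
        inits.append([math.log(mean), math.log(0.5)])
    return [np.asarray(v, dtype=float) for v in inits]


def _fit_least_squares(family: str, objective, mean: float, sd: float) -> PriorFit:
    best = None
    for x0 in _initial_vectors(family, mean, sd):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    spec = _spec_from_vector(family, best.x)
    return PriorFit(spec, float(best.fun))


def fit_to_roulette(judgement: RouletteJudgement, family: str) -> PriorFit:
    """Fit a parametric prior to roulette chips by least squares.

    Minimises ``sum_k (F(u_k) - F(l_k) - chips_k/total)**2`` over the family
    parameters, where ``(l_k, u_k]`` are the bin edges.
    """
    probs = judgement.probabilities
    if np.count_nonzero(probs) < 2:
        raise ValueError(
            "all chips fall in a single bin: the judgement is degenerate; use a point prior instead"
        )
    edges = judgement.bin_edges
    if family == "beta" and (edges[0] < 0 or edges[-1] > 1):
        raise ValueError("beta support (0,1) does not contain the roulette bins")
    if family == "lognormal" and edges[0] < 0:
        raise ValueError("lognormal support (0,inf) does not contain the roulette bins")
    if family == "point":
        raise ValueError("a point prior has no free parameters to fit")

    mids = 0.5 * (edges[:-1] + edges[1:])
    mean = float(np.sum(mids * probs))
    sd = float(np.sqrt(np.sum((mids - mean) ** 2 * probs)))

    def objective(x):
        try:
            d = _spec_from_vector(family, x).distribution()
        except (ValueError, OverflowError):
            return 1e6
        fitted = np.diff(d.cdf(edges))
        return float(np.sum((fitted - probs) ** 2))

    return _fit_least_squares(family, objective, mean, sd)


def fit_to_quartiles(judgement: QuartileJudgement, family: str) -> PriorFit:
    """Fit a parametric prior to elicited quartiles.

    The objective is the same probability-scale sum of squares as for the
    roulette format, ``sum_p (F(q_p) - p)**2`` over p in {0.25, 0.5, 0.75}.
    For the normal family the optimum has the closed form
    ``mean = q50``, ``sd = (q75 - q25) / (2 * 0.6745)`` when the elicited
    quartiles are symmetric.
    """
    q = np.array([judgement.q25, judgement.q50, judgement.q75])
    target = np.array([0.25, 0.5, 0.75])
    if family == "beta" and (q[0] <= 0 or q[-1] >= 1):
        raise ValueError("beta support (0,1) does not contain the quartiles")
    if family == "lognormal" and q[0] <= 0:
        raise ValueError("lognormal support (0,inf) does not contain the quartiles")
    if family == "point":
        raise ValueError("a point prior has no free parameters to fit")

    mean = float(q[1])
    sd = float((q[2] - q[0]) / (2 * _Z75))

    def objective(x):
        try:
            d = _spec_from_vector(family, x).distribution()
        except (ValueError, OverflowError):
            return 1e6
        return float(np.sum((d.cdf(q) - target) ** 2))

    return _fit_least_squares(family, objective, mean, sd)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _truncated_ppf_draws(dist, lower, upper, n, rng) -> np.ndarray:
    """Inverse-CDF draws restricted to (lower, upper); bounds may be arrays."""
    lo = dist.cdf(lower) if lower is not None else 0.0
    hi = dist.cdf(upper) if upper is not None else 1.0
    mass = np.asarray(hi) - np.asarray(lo)
    if np.any(mass <= 1e-14):
        raise ValueError("truncation bounds leave (numerically) zero prior mass")
    u = lo + rng.random(n) * mass
    # keep strictly inside the open interval
    u = np.clip(u, np.nextafter(np.asarray(lo, dtype=float), np.inf), np.nextafter(np.asarray(hi, dtype=float), -np.inf))
    return dist.ppf(u)


def sample_prior(spec: PriorSpec, n: int, rng_seed=None) -> np.ndarray:
    """Draw ``n`` independent samples from a (possibly truncated) prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_generator(rng_seed)
    if spec.is_point:
        v = spec.params[0]
        if spec.lower is not None and v <= spec.lower or spec.upper is not None and v >= spec.upper:
            raise ValueError("point prior value lies outside its truncation bounds")
        return np.full(n, v)
    return _truncated_ppf_draws(spec.distribution(), spec.lower, spec.upper, n, rng)


def joint_rates_sample(
    s1_prior: PriorSpec, rho_prior: PriorSpec, n: int, rng_seed=None
) -> tuple:
    """Joint draws of the survival rates (S1(t0), S2(t0)) in the two arms.

    S1(t0) is drawn from its prior; the survival difference rho = S2 - S1 is
    drawn from its prior truncated, per draw, to (-S1, 1 - S1) so that
    S2 = S1 + rho always lies in (0, 1).  rho is independent of S1 apart from
    this range restriction.
    """
    lo_s, hi_s = s1_prior.support()
    if lo_s < 0 or hi_s > 1:
        raise ValueError("the control-arm survival-rate prior must be supported on (0,1)")
    rng = as_generator(rng_seed)
    s1 = sample_prior(s1_prior, n, rng)
    lower = -s1
    upper = 1.0 - s1
    if rho_prior.lower is not None:
        lower = np.maximum(lower, rho_prior.lower)
    if rho_prior.upper is not None:
        upper = np.minimum(upper, rho_prior.upper)
    if rho_prior.is_point:
        v = rho_prior.params[0]
        if np.any(v <= lower) or np.any(v >= upper):
            raise ValueError("point prior for the survival difference leaves S2 outside (0,1)")
        rho = np.full(n, v)
    else:
        rho = _truncated_ppf_draws(rho_prior.distribution(), lower, upper, n, rng)
    s2 = s1 + rho
    return s1, s2
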