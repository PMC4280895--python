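import numpy as np
import pytest
from scipy import stats

from survassure import QuadratureGrid, SurvivalDataset, TrialDesign


@pytest.fixture
def km_data() -> SurvivalDataset:
    """Eight right-censored control-arm observations (the classic
    product-limit illustration)."""
    times = np.array([0.8, 1.0, 2.7, 3.1, 5.4, 7.0, 9.2, 12.1])
    events = np.array([1, 0, 0, 1, 1, 0, 1, 0], dtype=bool)
    return SurvivalDataset(times, events)


@pytest.fixture
def design_5yr() -> TrialDesign:
    """3-year accrual, 2-year follow-up design used in the exponential examples."""
    return TrialDesign.balanced(3.0, 5.0, 100)


@pytest.fixture
def design_10mo() -> TrialDesign:
    """5-month accrual, 5-month follow-up design used in the PH examples."""
    return TrialDesign.balanced(5.0, 10.0, 100)


@pytest.fixture
def grid_10mo(design_10mo) -> QuadratureGrid:
    return QuadratureGrid.for_design(design_10mo, 11)


def simulate_logrank_power(n_per_group, lam1, lam2, design, n_sim, rng) -> float:
    """Brute-force logrank rejection rate: exponential survival, uniform
    entry on (0, R), administrative censoring at T, standard (unweighted)
    logrank test per simulated trial."""
    z = stats.norm.ppf(1 - design.alpha / 2)
    n_tot = 2 * n_per_group
    lam = np.concatenate([np.full(n_per_group, lam1), np.full(n_per_group, lam2)])
    grp = np.concatenate([np.zeros(n_per_group), np.ones(n_per_group)])
    x = rng.exponential(1.0, (n_sim, n_tot)) / lam
    entry = rng.uniform(0, design.R, (n_sim, n_tot))
    follow_up = design.T - entry
    ev = x <= follow_up
    t = np.where(ev, x, follow_up)
    order = np.argsort(t, axis=1)
    ev_s = np.take_along_axis(ev, order, 1)
    g_s = np.take_along_axis(np.broadcast_to(grp, (n_sim, n_tot)), order, 1)
    at_risk = np.arange(n_tot, 0, -1)[None, :]
    at_risk_2 = np.cumsum(g_s[:, ::-1], axis=1)[:, ::-1]
    frac = at_risk_2 / at_risk
    u = np.sum(ev_s * (g_s - frac), axis=1)
    v = np.sum(ev_s * frac * (1 - frac), axis=1)
    return float(np.mean(np.abs(u / np.sqrt(v)) > z))


def simulate_exponential_test_power(n_per_group, lam1, lam2, design, n_sim, rng) -> float:
    """Brute-force rejection rate of the log-hazard-ratio test: per-arm MLE
    rates from (events, exposure), Wald statistic with variance 1/d1 + 1/d2."""
    z = stats.norm.ppf(1 - design.alpha / 2)

    def arm(lam):
        x = rng.exponential(1 / lam, (n_sim, n_per_group))
        entry = rng.uniform(0, design.R, (n_sim, n_per_group))
        follow_up = design.T - entry
        ev = x <= follow_up
        t = np.where(ev, x, follow_up)
        return ev.sum(1), t.sum(1)

    d1, t1 = arm(lam1)
    d2, t2 = arm(lam2)
    theta_hat = np.log((d2 / t2) / (d1 / t1))
    se = np.sqrt(1 / d1 + 1 / d2)
    return float(np.mean(np.abs(theta_hat / se) > z))
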