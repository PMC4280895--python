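"""Proportional-hazards assurance using censored historical control data.

Eight right-censored control-arm observations inform the control survivor
function through a Dirichlet-process prior (precision 1, exponential shape
anchored at 50% five-month survival); a Gibbs sampler handles the censoring.
The treatment effect enters as a prior on the 7-month survival difference.
The planned analysis is a logrank test after 5 months of uniform accrual and
5 further months of follow-up.
"""

from survassure import (
    DPPrior,
    PriorSpec,
    QuadratureGrid,
    TrialDesign,
    assurance_ph_with_data,
    event_probabilities,
    kaplan_meier,
    load_example_control_data,
    posterior_survivor_draws,
    power_logrank,
    theta_from_rates,
)

data = load_example_control_data()
km = kaplan_meier(data)
print(f"historical data: {data.n} records, {data.n_events} events")
print(f"Kaplan-Meier 7-month control survival: {km(7.0):.3f}")

theta = theta_from_rates(km(7.0), 0.175)  # hoped-for +17.5 point difference
print(f"log hazard ratio at the design point: {theta:.3f}")

design = TrialDesign.balanced(R=5, T=10, n_per_group=100)
grid = QuadratureGrid.for_design(design, n_nodes=11)
_, _, pe = event_probabilities(km(grid.nodes), theta, design, grid)
print(f"pooled event probability (Simpson, 11 nodes): {pe:.2f}")

prior = DPPrior.exponential_anchor(c0=1.0, t_anchor=5.0, s_anchor=0.5)
draws = posterior_survivor_draws(
    data, prior, grid, t0=7.0, n_iter=11_000, burn_in=1_000, rng_seed=3
)
print(f"posterior mean S1(7): {draws.t0_samples.mean():.3f}")

rho_prior = PriorSpec("normal", (0.175, 0.01))
for n in (100, 300, 2000):
    d = design.with_per_group(n)
    res = assurance_ph_with_data(draws, rho_prior, d, grid, rng_seed=4)
    pw = power_logrank(d.n_total, theta, pe, d)
    print(f"n/group {n:4d}: power {pw:.3f}, assurance {res.estimate:.3f} "
          f"+/- {res.se:.3f} (cap {res.prior_superiority:.3f})")
# The assurance plateaus below the prior probability of a positive survival
# difference, while the power keeps climbing to 1.
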