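"""Fitting priors to expert judgements: trial roulette and quartiles.

The trial-roulette format asks the expert to spread chips over equal-width
bins; chips / total is read as the probability of each bin.  The quartile
format asks for the lower quartile, median and upper quartile.  Both are
fitted by least squares on the probability scale, and the achieved sum of
squares is reported back to the expert as a goodness-of-fit check.
"""

import numpy as np

from survassure import (
    PriorSpec,
    QuartileJudgement,
    RouletteJudgement,
    fit_to_quartiles,
    fit_to_roulette,
    sample_prior,
)

# 20 chips on 10 bins spanning the plausible range (-0.1, 0.5) of a
# survival-rate difference
chips = [0, 1, 2, 3, 5, 4, 3, 1, 1, 0]
roulette = RouletteJudgement.from_range(-0.1, 0.5, chips)
fit = fit_to_roulette(roulette, "normal")
m, v = fit.prior.params
print(f"roulette fit: normal(mean {m:.3f}, sd {np.sqrt(v):.3f}), SSQ {fit.ssq:.2e}")

# quartiles for a control survival rate, fitted as a beta distribution
quartiles = QuartileJudgement(0.15, 0.20, 0.23)
qfit = fit_to_quartiles(quartiles, "beta")
a, b = qfit.prior.params
print(f"quartile fit: beta(a {a:.2f}, b {b:.2f}), SSQ {qfit.ssq:.2e}")

# truncated sampling: the difference prior restricted so S2 stays in (0,1)
# when the control rate is 0.6 -> bounds (-0.6, 0.4)
trunc = PriorSpec("normal", (m, v), lower=-0.6, upper=0.4)
draws = sample_prior(trunc, 100_000, rng_seed=1)
print(f"truncated draws: range ({draws.min():.3f}, {draws.max():.3f}), "
      f"P(difference > 0) = {np.mean(draws > 0):.3f}")
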