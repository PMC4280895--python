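# Methods

## The assurance framework

A two-arm trial (group 1 control, group 2 experimental) is planned with a
frequentist analysis whose success criterion is fixed in advance: reject the
two-sided null hypothesis of no treatment effect *with the data favouring
the experimental arm*. Assurance is the prior-averaged probability of that
outcome,

γ(N) = ∫ P(reject and favour group 2 | θ, N) f(θ) dθ,

estimated by Monte Carlo: draw effect parameters from the elicited prior,
evaluate the one-sided success probability analytically (exponential,
proportional hazards) or by simulating the trial outright (Weibull), and
average. Because the integrand is bounded by the indicator of a true
benefit, γ(N) ≤ P(prior superiority) for every N; reported results always
carry this cap alongside the estimate and a binomial Monte Carlo standard
error √(γ̂(1−γ̂)/M). The success direction is the single tail with the
estimated effect favouring group 2, i.e. Φ(−θ/se − z₁₋α/₂) rather than the
two-sided Φ(|θ|/se − z₁₋α/₂).

All randomness flows through one explicitly passed `numpy` Generator; no
global state. Defaults: M = 10⁵ prior draws for the analytic models
(se ≈ 0.0016), M = 2000 simulated trials for the Weibull model.

## Exponential model

Survival in arm *i* is exponential with rate λᵢ; patients enter uniformly on
(0, R) and are censored at total length T. The test is a Wald test of the
log median ratio θ = ln(m₁/m₂) = ln(λ₂/λ₁) with asymptotic variance
1/d₁ + 1/d₂ (dᵢ = events in arm *i*). At the design stage dᵢ is replaced by
its expectation Nᵢ·Pᵢₑ with

P(event) = 1 − [exp(−λ(T−R)) − exp(−λT)] / (λR),

the uniform-entry average of the probability of failing before follow-up
ends (evaluated in an `expm1` form that is stable as λ → 0). This closed
form is checked against numeric integration to 10⁻¹⁰ in the tests, and the
power formula is checked against a brute-force trial simulator (uniform
entry, administrative censoring, per-arm MLE rates, Wald statistic) at three
design points with several hundred expected events.

*Known limitation*: the formula is asymptotic in the event counts. At the
large-effect design point with 60% vs 80% five-year survival the power-0.8
trial expects only ~18 events in the experimental arm, and the simulated
rejection rate exceeds the formula by ~2.5 percentage points. With a few
hundred expected events the discrepancy is within Monte Carlo noise.

Priors: S₁(t₀) ~ beta, ρ = S₂(t₀) − S₁(t₀) ~ normal truncated per draw to
(−S₁, 1−S₁) so that S₂ stays in (0,1); rates follow via λᵢ = −ln Sᵢ(t₀)/t₀.
Alternatively the control rate can come from a **power-prior** gamma
posterior built from historical exponential data: Gamma(s₀ + a₀·events,
r₀ + a₀·exposure) with weight a₀ ∈ [0,1] (a₀ = 0 ignores the history,
a₀ = 1 weighs it fully); `assurance_exponential_historical` samples that
posterior in place of the survival-rate prior.

## Weibull model

Survivor convention S(t) = exp(−λtᵏ); shape κ and scale λ are recovered from
survival rates at two anchor times t₀ < t₀′ by

κ = ln(ln S(t₀′)/ln S(t₀)) / ln(t₀′/t₀),  λ = −ln S(t₀)/t₀^κ,

and the mean/variance of survival time are λ^(−1/κ)Γ(1+1/κ) and
λ^(−2/κ)[Γ(1+2/κ) − Γ(1+1/κ)²]. Moments are evaluated in log space
(`gammaln` + `log1p`) because prior draws occasionally produce shapes small
enough that Γ(1+2/κ) overflows naively; shapes below 10⁻³ are rejected
outright. The planned analysis compares mean survival times, which requires
complete follow-up — R and T play no role in this model and the design
contributes only group sizes and the test level.

Design-stage power uses the known-variance normal approximation; the
assurance simulates each candidate trial (N₁+N₂ complete Weibull times) and
applies Welch's t-test with Satterthwaite degrees of freedom, computed in a
scale-invariant form so heavy-tailed draws cannot overflow. Prior
superiority is decided on log-mean survival for the same reason.

Priors are placed on four observables: S₁(t₀), the control drop
S₁(t₀)−S₁(t₀′), the between-arm difference S₂(t₀)−S₁(t₀), and the
experimental drop S₂(t₀)−S₂(t₀′), drawn sequentially with each component
truncated so all four rates stay in (0,1) and both survivor curves decrease
(truncation order: control drop given S₁(t₀); between-arm difference given
S₁(t₀); experimental drop given S₂(t₀)). An odds-ratio parameterisation
(lognormal priors on within- and between-arm odds ratios) is available as a
flag; with odds ratios the between-arm component needs no truncation at all.

*Known limitation*: with shapes around 0.4–0.5 the survival times are so
skewed that the CLT for the sample mean converges slowly; near power 0.8 the
normal-approximation power is accurate to ~1 percentage point at 200
patients per arm, but at higher power levels it can understate the simulated
rejection rate by ~2 points. The simulation-validation tests therefore use
moderate-skew design points (shapes 0.8–1.2) for the tight 2.5-SE check and
bound the heavy-skew case at 0.03 absolute.

## Proportional hazards model

The logrank-test power is Φ(|θ|√(N·Pₑ·Q₁Q₂) − z₁₋α/₂), depending on the
design only through the expected event count N·Pₑ. The pooled event
probability combines per-arm probabilities

P₁ₑ = 1 − (1/R)∫_{T−R}^{T} S₁(u) du,  P₂ₑ = 1 − (1/R)∫ S₁(u)^{exp θ} du,

evaluated by composite Simpson quadrature on an odd number of equally spaced
nodes on [T−R, T] (default H = 11; the worked example's pooled value 0.42 is
tied to this node count — exact integration of the step function gives
≈0.415). Survivor draws are evaluated right-continuously at the nodes (the
Kaplan–Meier convention); quadrature on step functions can over/undershoot
slightly, so probabilities are clipped to [0,1] with a warning. The log
hazard ratio is tied to the anchor-time survival rates by
θ = ln(ln(S₁(t₀)+ρ)/ln S₁(t₀)).

Without historical data, beliefs are elicited directly about P₁ₑ, S₁(t₀) and
ρ. The curve shape needed inside P₂ₑ is then unidentified; the package takes
S₁ to be exponential through the sampled P₁ₑ (rate solved by Brent's method
from the uniform-entry identity), under which P₂ₑ has the exponential closed
form with rate λ·e^θ. This choice is isolated in one function and documented
here because the elicitation pins down only P₁ₑ, not the curve.

With historical data, the control survivor gets a **Dirichlet-process
prior** with precision c₀ and shape survivor G (default: exponential through
one elicited anchor, e.g. G(5) = 0.5 ⇒ rate ln 2/5). The time axis is
partitioned by the quadrature nodes, the distinct censoring times and the
anchor t₀ (duplicates merged); interval probabilities are a priori
Dirichlet with parameters c₀·(G-increments). Although the quadrature lives
on [T−R, T], the partition starts at 0 so that observed times before T−R
remain usable, and ends with an open tail interval. Right censoring breaks
conjugacy, so a two-block Gibbs sampler alternates (i) multinomial
imputation of each censored record into the intervals beyond its censoring
time, with probabilities proportional to the current interval masses, and
(ii) a conjugate Dirichlet redraw given the completed counts. Chains start
from the prior-mean probabilities; defaults are 11 000 iterations with
1 000 burn-in and no thinning — the chain is a low-dimensional Dirichlet
and mixes essentially immediately (the uncensored case is iid). Survivor
values are tail sums of the probability vector, which makes every draw
monotone by construction; S₁(t₀) is the tail sum at the t₀ cut point
(a step-function convention — values between cut points take the
right-boundary value).

Ties between event and censoring times follow the Kaplan–Meier events-first
convention. A censored record with no probability mass beyond it is imputed
into the tail interval with a warning.

## Elicitation and truncation

Both judgement formats are fitted by least squares on the probability scale:
roulette minimises Σₖ(F(uₖ)−F(lₖ) − chipsₖ/total)² over bins, quartiles
minimise Σₚ(F(qₚ)−p)² over p ∈ {¼, ½, ¾}. One objective for both formats
keeps the feedback (the achieved SSQ) comparable. The optimiser is
Nelder–Mead on an unconstrained log/logit-free parameterisation
(log-positive parameters), multi-started from moment-matched initial values
because beta SSQ surfaces can be nearly flat along the concentration
direction; tolerances 10⁻¹⁰/10⁻¹². A judgement with all chips in one bin is
rejected as degenerate (use a point prior), and families whose support does
not contain the bins or quartiles are rejected.

Truncated sampling is exact inverse-CDF on the renormalised range — draw
u ~ U(F(lower), F(upper)) and apply F⁻¹ — never rejection or clipping, so
per-draw bounds (which depend on other sampled quantities) cost nothing.

## Synthetic data

`simulate_survival_dataset` generates what the designs assume: entry
~ U(0, R), survival from the stated exponential or Weibull model,
administrative censoring at T, times on the patient clock. It reproduces the
closed-form event probabilities to Monte Carlo accuracy and is what the
validation oracles are built from. It does **not** emulate loss to
follow-up, non-uniform accrual, covariates or treatment switching, so
passing tests say nothing about those features of real trials; the
historical-data pathway is exercised on an eight-record dataset, which is
deliberately small and makes the posterior spread (sd of S₁(7) ≈ 0.18)
a genuine feature of the examples, not an artefact.

## Numerical choices and problem sizes

- Sample-size search: smallest integer N per group with power ≥ target,
  bracketing by doubling then integer bisection (power is monotone in N).
- Assurance curves reuse one set of prior draws across the whole N grid
  (common random numbers), so curves are smooth in N and the Monte Carlo
  SE applies pointwise.
- Gauss–Hermite quadrature (60 probabilists' nodes) provides an independent
  evaluation of the assurance integral when only θ is uncertain and Pₑ is
  fixed; the test suite requires MC and quadrature to agree to 3 decimals.
- Test-suite problem sizes are chosen so the whole suite runs in well under
  a minute: 10⁵–10⁶ draws for distributional checks, 5–10×10³ simulated
  trials per power-validation point, 2×10⁴ Gibbs iterations for the
  conjugacy check.

## Known limitations

- The exponential and logrank power formulas are asymptotic in event counts
  (see above); the Weibull normal approximation degrades for shapes ≪ 1.
- The Dirichlet-process machinery models the control arm only; the
  experimental arm enters solely through the proportional-hazards link.
- Multi-expert pooling, interim analyses, non-uniform accrual and
  stratified/weighted logrank tests are out of scope.
- With t₀ between partition cut points, S₁(t₀) uses the right-boundary tail
  sum; the package merges t₀ into the partition precisely to avoid this
  mattering, but user-supplied draws evaluated elsewhere inherit the step
  convention.
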