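# Methods

## The model

`aemeta` analyses *aggregate* adverse-event data from controlled trials:
one row per arm with sample size `n`, number of patients with at least one
event of interest `y`, number of early discontinuations `z`, number of
fatal events `m`, and maximum follow-up `tau`.

At the patient level the model assumes an exponential time to first event
`X ~ Exponential(lambda)`, an exponential time to drop-out
`C ~ Exponential(mu)` (which may also represent competing events such as
disease progression), and an independent fatality flag `M ~ Bernoulli(q)`.
Every patient then falls into exactly one of five timeline categories —
fatal event; nonfatal event and completion; nonfatal event then drop-out;
administrative censoring; drop-out before any event — whose closed-form
probabilities `p1..p5` follow from the three distributions.  The published
counts identify the category counts only partially: `m = w1` is observed,
and the nonfatal-event-then-drop-out count `w3` is latent within the range
`[max(0, y+z-m-n), min(y-m, z-m)]`.  The arm likelihood is the multinomial
probability summed over that range; the package computes it with log-gamma
factorials and log-sum-exp, so it is exact to floating-point precision for
any `n` (a brute-force enumeration oracle in the test-suite confirms
agreement to 1e-10 up to `n = 8`, and that the probabilities of all
achievable `(y, z, m)` triples sum to 1).

Across trials the log rates are exchangeable:

    log(lambda_anchor_i) ~ Normal(nu1, sigma1^2)
    log(mu_i0)           ~ Normal(nu2, sigma2^2)
    log(mu_i1)           ~ Normal(nu3, sigma3^2)

with the *anchor* arm chosen per analysis: control-anchored
(`log lambda_i1 = log lambda_i0 + phi_i`) by default, or
treatment-anchored (`log lambda_i0 = log lambda_i1 - phi_i`) when the
control arms are the heterogeneous ones, as in the packaged oncology
example where the same compound is compared against different controls
across indications.  The common-effect (CE) model sets `phi_i = phi`; the
random-effects (RE) model draws `phi_i ~ Normal(phi, eta^2)` and reduces
to CE at `eta = 0` (asserted numerically in the tests).  Fatality
probabilities `q0, q1` are shared across trials.

### Priors

The vague menu is `Normal(0, 100^2)` for locations, `Halfnormal(100)` for
scales, and Jeffreys `Beta(0.5, 0.5)` for proportions.  For the log hazard
ratio the menu offers `Cauchy(0, 2.5)` (weakly informative) and
`Cauchy(0, 0.37)` (90% prior mass on hazard ratios between 0.1 and 10).
For the heterogeneity `eta` the half-normal scale ranges over
`{0.1, 0.25, 0.5, log 10, 100}`.  A weakly informative menu for
type-2-diabetes-like settings (`nu1 ~ Normal(-4.27, log(10)^2)`,
`nu2, nu3 ~ Normal(log 0.22, log(10)^2)`, scales `Halfnormal(log 10)`) is
provided as `ModelSpec.rosiglitazone_weakly_informative()`.

### Borrowing from historical controls

`fit_historical` fits the control-only hierarchy to historical single-arm
trials; `map_predictive` returns either the hyperparameter posterior
(*non-stratified* borrowing, which lets current trials shrink towards each
other) or the new-trial predictive for `(log lambda_0, log mu_0)`
(*stratified*, no cross-trial shrinkage); `fit_mixture` approximates each
margin with at most three parametric components (normal on the real line,
zero-truncated normal for scales, beta for proportions), selected by BIC,
with the Kolmogorov-Smirnov distance recorded; `robustify` mixes in a
vague component with 50/80/100% informative weight.  Margins are
approximated by *independent* univariate mixtures, the standard
meta-analytic-predictive practice; `map_predictive` exposes the raw joint
draws for sensitivity analyses that want to preserve correlations.  The
hyperparameters informed by historical data are `nu1, sigma1, nu2, sigma2,
q0`; the treatment-arm drop-out level and `q1` keep their vague priors
(configurable), since historical controls carry no information about them.

## Posterior computation

No general-purpose probabilistic-programming backend is used; the sampler
is a purpose-built composition of Metropolis kernels on a flat parameter
vector, compiled with numba:

* **Parameterization.** Trial-level log rates are sampled *centered*: the
  aggregate counts identify them tightly, so the centered geometry is
  nearly independent, whereas non-centered deviates couple strongly to
  their scale hyperparameters (in experiments the centered form improved
  the effective sample size of the pooled log-HR by roughly three orders
  of magnitude on the oncology data).  Fatality probabilities are sampled
  on the logit scale with the beta prior's Jacobian; scales on their
  natural nonnegative scale.  A non-centered build remains available
  (`CompiledModel.build(..., parameterization="non-centered")`).
* **Global moves.** When the ensemble has at least `2 (dim + 1)` walkers,
  affine-invariant stretch moves and differential-evolution moves
  (`gamma = 2.38 / sqrt(2 dim)`, 10% mode-hopping jumps) act on the full
  vector using the complementary half of the ensemble.
* **Trial-local moves.** The posterior factorizes into per-trial blocks
  given the globals; each sweep applies, per block, a joint shift of the
  block's log rates — the near scale-invariant `(lambda, mu)` ridge that
  appears when drop-out saturates (`z ~ n`) — and a single-coordinate
  differential-evolution or random-walk move.  Both re-evaluate only that
  trial's arms via cached block likelihoods.
* **Gibbs rejuvenation.** With centered trial levels, the hyperparameters
  `(nu_k, sigma_k)` and, in the RE model, `(phi, eta)` are conditionally
  independent of the data; they are updated by exact univariate slice
  sampling of their full conditionals.
* **Collective level moves.** The RE log-HR level mixes slowly under
  purely local updates, so two interweaving-style moves act on it: a joint
  shift of `phi` and all `phi_i`, and a joint rescaling of `eta` and the
  `phi_i` fan around `phi` (the non-centered `phi` and `eta` updates at
  fixed deviates; the rescaling carries a `c^(T+1)` Jacobian).  Under CE,
  a random walk on `phi` and a joint `phi`-with-anchors shift play the
  same role.  The logit fatality probabilities get their own heavy-tailed
  random-walk refresh (their left tail is long when no fatal events are
  observed).
* **Adaptation.** Proposal scales adapt by diminishing Robbins-Monro
  steps towards ~35% acceptance during burn-in only; the post-burn-in
  kernel is fixed, so the chain is valid MCMC.  All randomness derives
  from the user seed; runs are bit-reproducible.

`emcee`'s independent implementation of the stretch move is used in the
test-suite as a cross-check oracle on a small model; the two samplers
agree on the posterior quartiles of the data-identified parameters.

Convergence is monitored with the rank-normalized split R-hat and bulk
effective sample size (via `arviz`; an independent implementation of the
published R-hat formula is part of the test-suite).  A fit raises a
warning flag when any parameter exceeds R-hat 1.01.  The default protocol
is 5 chains, 10 000 burn-in sweeps, thinning 5, ~10 000 retained draws;
`burn_in` and `thin` count ensemble sweeps (one update of every walker),
and `kept` is the total retained draw count pooled over chains and
walkers.

Point estimates are posterior medians (invariant under the log-HR to HR
transform); intervals are 95% equal-tailed pooled-chain quantiles; the
rejection rule for type-I-error and power is two-sided at 5% (0 outside
the 95% CI for `phi`).  Hazard-ratio-scale outputs are the exponentiated
quantiles of `phi`, which for equal-tailed intervals coincide with the
quantiles of the exponentiated draws.

A power-scaling prior-sensitivity hook is deliberately not implemented;
the posterior draws and the declarative prior objects expose everything
such a diagnostic needs, and `PosteriorSamples.to_dataframe()` exports the
draws for external tooling.

## The simulator and what it does (not) emulate

`simulate_program` draws per-trial parameters from the hierarchy above
and per-patient timelines from the three generative distributions, then
aggregates to the published schema; by construction the simulated rows
always satisfy the aggregate-data invariants, and the per-category
frequencies converge to the closed-form probabilities (chi-square
goodness-of-fit at 10^6 patients in the tests).  A Weibull shape knob
(`S(t) = exp(-(lambda t)^shape)`) allows violating the exponential
assumption; `shape = 1` reproduces the exponential pathway draw for draw
under the same seed.  The simulator does not model staggered entry,
informative drop-out, recurrent events, or reporting heterogeneity —
passing operating-characteristic checks therefore validates the method
under its own assumptions, not against those real-data complications.

Two preset scenario families are shipped:

* **Development-program preset** (`rosiglitazone_scenario`): six two-arm
  trials totalling 1425 patients — 12-week trials randomized 6:1
  (300:50) and 1:1 (150:150), three half-year 2:1 trials (150:75), one
  1-year 1:1 trial (50:50) — plus 12 historical single-arm control trials.
  The per-trial sizes within the published ranges, and the historical
  trials' size (100 patients) and duration (half a year), are this
  package's interpretation where the source layout leaves them open.
  Truth: `lambda_0 = mu_0 = mu_1 = 0.5`/year, `q0 = q1 = 0.35`,
  control-anchored, `phi` and `eta` per scenario.
* **Oncology preset** (`oncology_scenario`): nine two-arm trials whose
  arm sizes and follow-up durations copy the packaged example data;
  treatment-anchored with `log lambda_i1 ~ Normal(log 0.02, 1.2^2)`,
  `mu = 0.5`, `q0 = q1 = 0.01`, so the control arms inherit the larger
  variance `Var(log lambda_i0) = Var(log lambda_i1) + Var(phi_i)`.
  **Time unit:** the preset interprets the rates per *year* and converts
  the published follow-up months to years.  On a month scale a drop-out
  hazard of 0.5 would empty every arm (`z = n` throughout) and leave the
  hazard ratio barely identified; on the year scale the simulated event
  fractions (0-8%) and discontinuation fractions (~0.3-0.95) reproduce
  the observed margins of the example data, which the scenario is meant
  to mimic.

## Operating characteristics

`run_oc` simulates a program per replicate, refits every requested model,
and scores coverage of the true `phi`, rejection of 0, bias and RMSE of
the point estimate.  Borrowing models re-derive a robustified MAP prior
(non-stratified, 50% informative weight) from the replicate's own
simulated historical arms.  Per-replicate RNG substreams descend from the
master seed, so results do not depend on execution order.  Replicates
whose `phi` R-hat exceeds 1.1 are counted and excluded, never silently
dropped; the threshold is generous because the split-half R-hat estimate
itself is noisy at a few hundred effective draws.

The desk-scale protocol (`OC_MCMC_DEFAULT`) uses 200 replicates with a
single 10-walker ensemble per fit, 250 burn-in sweeps and ~300 retained
sweeps (~3000 draws per fit).  At that scale the Monte-Carlo standard
error of a coverage estimate is ~1.5 percentage points, which is adequate
for the package's calibration checks; full-scale reproduction (1000
replicates, the default fitting protocol) is a cluster- or overnight-size
computation exposed through the same API and CLI.

## Known limitations

* The likelihood assumes constant (exponential) hazards; the Weibull knob
  exists only in the simulator, to *study* that violation, not in the
  fitted model.
* With very few historical trials the hyperparameter posteriors are
  heavy-tailed and the independent-margin mixture approximation of the
  MAP prior is crude (the KS distance in the provenance flags this).
* Arms with `z = n` (no completers) make `(lambda, mu)` jointly
  unidentified up to a common scale; the sampler handles the ridge, but
  such datasets genuinely carry little information about the hazard
  ratio.
* The rank-R-hat screen on a single-ensemble fit splits walkers over
  time; it detects drift and poor mixing but not multimodality missed by
  all walkers simultaneously.
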