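# Methods

## Model

`ministep` implements a stochastic actor-oriented model (SAOM) for the
joint dynamics of a directed friendship network `x` (binary adjacency,
no self-ties) and an ordinal behavior `z` (BMI category, 11 levels)
observed at two or more waves. The observed waves are treated as
snapshots of a continuous-time Markov chain. Within a period of unit
length, each of the `n_active` participating actors carries two
exponential clocks with rates `λ_net` and `λ_beh` (per-period
parameters). When a clock fires, the actor makes one *ministep*: either
toggles one outgoing tie (the no-change alternative is always in the
choice set) or moves the behavior one category up or down (staying is
allowed; moves that leave the 1–11 range are excluded). Alternatives
are weighted by a multinomial logit on a linear evaluation function
`f_i = Σ_k β_k s_ik`, with separate effect sets for the network and the
behavior choice.

Assumptions inherited from this family of models: change is
actor-driven and one micro-change at a time; rates are constant within
a period and identical across actors; the evaluation function is
myopic (no anticipation); covariates are constant over the study.

## Coding and centering

* BMI (kg/m²) maps to codes 1–11 at cut points 19, 20, …, 26, 28, 31.
  The mapping is total on (0, ∞) and weakly monotone; non-positive or
  non-finite inputs are rejected.
* Behavior codes are mean-centered with a single constant pooled over
  all non-missing actor-wave observations (a single constant is what
  makes one centered scale, e.g. −5.25…+4.75, meaningful across waves).
  The scale's `range` is the observed max − min (10 when the extreme
  categories both occur).
* Numeric actor covariates enter effects centered over all actors;
  quadratic effects square the centered value. `same` effects compare
  raw labels.
* The dyadic similarity score `sim_ij = 1 − |z_i − z_j|/range` is
  centered by a constant `sim_c`; in data analyses it defaults to the
  mean similarity over all ordered pairs with observed behavior, pooled
  across waves, and it is 0 in toy settings. `sim_c` shifts only the
  baseline attractiveness of the no-change alternative (a rate-like
  quantity), not the influence coefficient's meaning.

## Effect conventions

Named variants are fixed as follows so toy counts are reproducible:

* transitive triplets for actor `i` counts ordered pairs `(j, h)` with
  `i→j`, `i→h`, `h→j` (the tie `i→j` closes the two-path through `h`);
  on a complete digraph this is `(n−1)(n−2)` per actor.
* the reciprocated variant additionally requires `j→i`.
* out-degree activity is the square of the out-degree; in-degree
  activity is out-degree × in-degree (the plain, non-square-root
  variants).
* average similarity is `(1/d_i) Σ_j x_ij (sim_ij − sim_c)` and is
  defined as 0 for actors with no outgoing ties.

Every effect has a closed-form *change statistic* (its delta under a
single tie toggle or behavior step), vectorized over the `n` toggle
targets. The test suite verifies these against full recomputation for
every effect, actor, and admissible change on random graphs with up to
six actors — brute force is the oracle, the vectorized forms the
implementation.

## Missing data

An actor absent at a wave has missing behavior, contributes no outgoing
ties at that wave, and keeps incoming nominations. For simulation
starts, behavior is imputed by last-observation carry-forward (backward
fill before the first observation). Imputed actor-wave observations are
excluded from the moment targets and from the rate targets (network
change counts only dyads whose ego is observed at both ends of a
period; behavior change only actors observed at both ends), so that
imputation cannot masquerade as observed change. Period simulations
activate the actors participating at the period's start wave.

## Estimation

Method of moments: for every effect, the target is the statistic summed
over observed end-wave actors across periods; for every rate, the
observed amount of change in its period (tie flips; total |Δz|). The
estimate solves `E_θ[S] = s_obs`, where each period is simulated from
its *observed* start wave (unconditional dynamics: simulation is not
conditioned on the observed amount of change).

Three phases:

1. **Derivative.** `7 + 3p` simulations at the start value estimate
   `D = ∂E[S]/∂θ` by the likelihood-ratio identity `cov(S, g)`, where
   `g` is the gradient of the simulation log-probability (logit score
   contributions per ministep; `K/λ − n_active` for the rates). A
   finite-difference check of this estimator on a small model agrees
   entry-wise.
2. **Robbins–Monro.** Iterations `θ ← θ − a D⁻¹ (S − s_obs)` over four
   subphases with the gain `a` halved each subphase (default initial
   gain 0.2) and the subphase average carried forward. Safeguards,
   needed because single-draw deviations are noisy and some directions
   (notably average similarity at small n) are weakly identified: the
   first subphase uses only the diagonal of D; diagonal entries smaller
   than 0.25 × the statistic's SD — in particular negative estimates,
   which must be noise since every statistic is increasing in its own
   parameter — are floored and the parameter decoupled for that
   subphase; standardized deviations are truncated at 4 SD; steps are
   capped elementwise (default 2.0); rates are floored at 0.05. D is
   re-estimated from each subphase's draws when they number at least
   `2p` and yield a positive diagonal. None of these change the fixed
   point: any positive-definite preconditioner leaves the root of the
   moment equations where it is.
3. **Diagnostics.** `n3` (default 500) simulations at the final θ give
   per-statistic convergence t-ratios (mean deviation / SD), an overall
   ratio `sqrt(d̄ᵀ Σ⁻¹ d̄)`, the parameter covariance `D⁻¹ Σ D⁻ᵀ`, and
   `se = sqrt(diag)`. Convergence is declared when every |t| < 0.1 and
   the overall ratio < 0.25; otherwise a warning is raised (never
   silently accepted) and, if `n_restarts` > 0, the phases rerun from
   the obtained θ — the standard remedy for a fit that has moved toward
   but not yet settled on the solution.

Starting values: rates from observed per-actor change counts, the
out-degree coefficient from the observed density logit, all other
coefficients zero. A numerically singular derivative matrix aborts with
its condition number rather than producing garbage. Estimation is
bit-for-bit reproducible given (panel, spec, options, seed). Wald tests
are `z = θ̂/se` with two-sided normal p-values.

## Interpretation

* Network coefficients convert to single-tie odds ratios `exp(β)`.
* The alter-selection curve is `g(v) = β_alter v + β_alterSq v²` over
  the centered category grid, with vertex `−β_alter/(2β_alterSq)` when
  the parabola opens downward; grid points carry the kg/m² band labels.
* Behavior-change odds ratios compare one-category moves (vs. staying)
  between two friend configurations through the full evaluation-function
  change. The canonical contrast puts all friends one category above
  the ego versus a "same or lower" baseline. For an *increase*,
  baselines with friends at the ego's category or one below give
  identical odds (either way the step moves the ego away from the
  friends' mean), which is what makes "same or lower" a single
  reference class; for a *decrease* the baseline uses friends one
  category below, so the step moves toward them. With this pairing the
  increase and decrease ratios are exact inverses and reduce to
  `exp(±2 β_avsim / range)` — the shape terms cancel. The per-own-
  category factor on the increase-vs-stay odds is `exp(2 β_quad)`.
* Uncertainty in any scalar functional of θ is propagated by a Monte
  Carlo bootstrap: draws from `N(θ̂, cov)` mapped through the functional,
  2.5/97.5 percentiles reported; default 10⁵ draws, seeded.

Display rounding follows the reporting convention (1 decimal for
network odds ratios, 2 for behavior); full precision is kept internally.

## Synthetic studies

The generator emulates the study conditions of a one-residence-hall
panel: 276 actors, four waves over an academic year, participation
239/241/218/192, covariate marginals (71.0% female; race fractions
White 0.490 / Hispanic 0.272 / Other 0.134 / Black 0.105, normalized;
93.1% first-year), wave-1 BMI category frequencies from the observed
distribution, and a wave-1 network calibrated to a mean within-hall
out-degree of 3.3 with floor clustering (multiplier 1.5 on same-floor
dyads, matching the fitted same-floor odds ratio) and a reciprocation
pass (probability 0.4 of closing an asymmetric dyad — chosen once as a
realistic value; the source data report no initial-wave reciprocity).
Floors number 10, a typical large-hall layout. The wave-1 generator is
deliberately a simple inhomogeneous Bernoulli model, not a SAOM draw:
estimation conditions on the first wave, so only its moments matter.
The co-evolution forward simulation uses the fitted no-demographics
parameter vector as the true θ. Missingness is completely at random
subject to exact per-wave counts and every actor keeping ≥ 2 observed
waves.

What the generator does **not** emulate: the ranked top-5-male /
top-5-female nomination instrument (ties are unranked), demographic
assortment in the initial network beyond floors, non-random response
mechanisms, and measurement error in anthropometry. Passing tests on
synthetic panels therefore validate the machinery and the estimator's
statistical behavior, not the substantive conclusions on any real
cohort.

## Problem sizes in the test suite

The suite exercises full-size generation (n = 276) but keeps
simulation-heavy estimation checks at desk scale, chosen once as the
package's default verification sizes: structural-recovery tests use
panels of 30–50 actors over 2–3 periods with reduced Robbins–Monro
schedules (subphase starts of 25–40 iterations, phase-3 batches of
150–300), and the synthetic-recovery acceptance check runs four
replicate studies of 50 actors with the fitted structural parameters,
requiring every parameter within three reported standard errors in at
least three of four replicates. Monte Carlo tolerances are stated in
each test in units of the relevant standard error.

## Known limitations

* Rates are constant across actors and within periods; no
  covariate-dependent rate functions.
* Evaluation-only objective functions: no endowment/creation asymmetry,
  no time-heterogeneous coefficients.
* Estimation is unconditional; the conditional variant (fixing observed
  change counts) common in this model family is not implemented, so
  rate estimates can differ slightly from conditional fits.
* The average-similarity coefficient is weakly identified in small or
  sparse panels — expect wide standard errors there; the estimator
  guards against the resulting numerical instability but cannot create
  information that is not in the data.
* `same` effects accept any covariate whose labels support equality;
  applying them to a continuous covariate is syntactically possible but
  substantively meaningless.
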