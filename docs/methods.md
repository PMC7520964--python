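# Methods

`parage` estimates how the risk of ten neonatal morbidity/mortality (NMM)
outcomes varies with maternal and paternal age at one-year resolution,
and how much of that risk is carried by chromosomal disorders (Down
syndrome, DS, and other chromosomal disorders, CD).  This note documents
the models, the sampler, the synthetic-data generator, and the design
choices that were genuinely open.

## Data model and exclusion rules

The unit of analysis is a singleton birth record: integer parent ages,
DS/CD flags, ten binary outcomes (preterm <37w, very preterm <32w, SGA,
Apgar <4, NICU admission, antibiotics, surfactant, prolonged ventilation,
seizures, in-hospital death), optionally birthweight (g) and gestational
length (days).  Analysis cohorts retain records with maternal age in
15–49, paternal age in 15–65 and all ten outcomes observed.  The audit
report tallies each deleted record in exactly one category with the
precedence mother-under → mother-over → father-missing/out-of-range →
missing-outcome; parent-age rules are applied before the outcome rule so
the categories partition the deletions and the conservation identity
`input = retained + deletions` holds exactly.  A missing maternal age is
counted with the under-minimum category (it cannot be placed against a
bound; the choice only affects which audit cell it lands in, not whether
it is deleted).

SGA is derived as birthweight strictly below the empirical 10th
percentile of birthweight among births with the same gestational length
in days.  The percentile uses linear interpolation between order
statistics; this convention is deterministic and documented because the
source definition does not fix one.  Days with fewer than 10 births still
get a threshold, with a logged warning.  By construction roughly 10% of a
large continuous-weight group is flagged.

## The age-risk model

For one outcome, case counts `Y_c` and birth counts `n_c` are
cross-tabulated by single year of age — one axis (35 maternal or 51
paternal levels) or the complete 35×51 grid — and modelled as

    Y_c ~ Binomial(n_c, mu_c)
    logit(mu_c) = alpha + maternal_i [+ paternal_j]

with a flat improper prior on `alpha` and a first-order random-walk (RW1,
the 1-D intrinsic CAR) prior on each per-age effect vector:

    log p(effect | sd) = -(K-1) log sd - sum_a (effect_{a+1} - effect_a)^2 / (2 sd^2)

with `sd ~ Uniform(0, 10)` (the bounds are configurable; a narrow bracket
effectively fixes `sd`, which the test oracle exploits).  The RW1 prior
shrinks adjacent ages toward each other without imposing a parametric
shape; when the data carry no information about adjacent-age correlation
the fit degrades gracefully toward the independent-age model.

Identifiability: the flat intercept plus the shift-invariant RW1 leave
one flat direction per axis.  After every sweep each axis's effect vector
is recentred to sum to zero and the removed mean is absorbed into
`alpha`.  All reported quantities (ORs standardized to a reference age)
are invariant to this choice.

### Model presets

* `total_maternal` / `total_paternal`: univariate model on the full
  filtered cohort — the total effect of that parent's age.
* `adjusted_maternal`: joint model restricted to DS/CD-negative neonates —
  adjusts for paternal age (confounding through the parent-age
  correlation) and removes the DS/CD mediation pathway.
* `adjusted_paternal`: joint model on all data — DS/CD can confound but
  does not mediate paternal age (it is driven by maternal age, which is
  in the model), so no restriction is applied.

### Sampler

Adaptive single-site Metropolis-within-Gibbs: Gaussian random-walk
proposals for `alpha` and each age effect (sites updated in an even/odd
checkerboard so each coloured block vectorizes while remaining a sequence
of single-site updates — the RW1 prior couples only adjacent sites), and
a log-scale random-walk for each `sd` with hard rejection outside its
bounds, which respects the uniform prior exactly.  Proposal scales adapt
in batches of 50 during burn-in only, targeting 0.44 acceptance, and are
frozen afterwards so the retained chain is Markovian.

Two auxiliary Metropolis moves per axis are essential for the weakly
identified directions of an intrinsic random-walk field:

* **rescale** — propose `(sd, effects) -> (g·sd, mean + g·(effects -
  mean))` with log-normal `g`.  The RW1 prior exponent is invariant under
  this map (acceptance ratio `likelihood-ratio × g`), so where the data
  are weak the hyperprior scale mixes freely instead of creeping behind
  the effect field.  Without it, the no-data posterior of `sd`
  (analytically Uniform(0,10)) shows effective sample sizes near 1.
* **spectral** — perturb the effect vector along one discrete-cosine
  eigenvector of the RW1 precision, with proposal scale proportional to
  that mode's prior SD `sd / (2 sin(pi m / 2K))`.  This refreshes the
  slow long-wavelength modes, e.g. paternal ages 60–65 where almost no
  births occur and single-site updates relax only diffusively.

Chains start from deliberately disparate states: chain c's intercept at
the empirical overall logit plus an offset `2c·(-1)^c`, effects at zero,
`sd` spread over its support.  Defaults mirror the study protocol: 2
chains, 5,000 burn-in, 200,000 iterations keeping every 100th (2,000
draws per chain).  Tests and the demo use much shorter chains; the
problem sizes used by each experiment are stated below.  Runs are
bit-reproducible from the seed.

Convergence is summarized by split-R̂ (each chain halved; flagged
converged when max R̂ < 1.05) and a Geyer initial-positive-sequence
effective sample size.  Rank normalization is deliberately not applied so
that two identical stationary chains give R̂ = 1, which the tests assert;
an arviz cross-check test keeps the two implementations honest.
Convergence failure in the CLI is a prominent warning, not an error —
results are still written so the user can extend the chain.

### Verification oracle

`grid_posterior_oracle` integrates the posterior (with `sd` fixed) by
dense quadrature on a tensor grid over `(alpha, effects)` with the
sum-to-zero constraint substituted in, centred on the mode with
half-width 6 Laplace SDs and 41 points per dimension.  It refuses spans
longer than 4 ages.  Its discretization-error estimate is the largest
moment change against a half-resolution grid; refining the grid shrinks
it.  The MCMC sampler is required to reproduce the oracle's posterior
means within 0.02 on all fixtures.

## Odds-ratio reporting

DS/CD exposure ORs use the exact conjugate route: each arm's rate has a
Uniform(0,1) prior, hence a Beta(Y+1, n−Y+1) posterior; OR draws are the
ratio of the two arms' odds, summarized by the median and central 95%
interval (100,000 seeded draws by default; the Monte-Carlo error of the
median is far below the reported 2-decimal precision).

Age curves are standardized draw-wise: `OR_a = exp(effect_a −
effect_ref)`, median and 2.5/97.5 percentiles per age, reference age 15
for figures and the trough ages (maternal 30, paternal 35) for tabular
contrasts.  The per-age "significance" probability is the two-sided
posterior tail probability `min(1, 2·min(P(OR ≥ 1), P(OR ≤ 1)))` — the
operational reading of a posterior-predictive p-value when no replicate
discrepancy statistic is specified; the ≥/≤ convention makes the
reference age's probability exactly 1.  No multiplicity adjustment is
applied across the ten outcomes.

### Shape classification

The trough is the age with the lowest posterior-median OR (ties go
youngest).  With S(a,b) = "OR_a/OR_b has two-sided tail probability <
0.05 and median ratio > 1":

| young vs trough | old vs trough | old vs young | label |
|---|---|---|---|
| S | S | S | J |
| S | S | not S | U |
| not S | S | — | increasing |
| S | not S | — | decreasing |
| not S | not S | — | flat |

"Mid-range" is operationalized as the posterior trough because no
sharper definition is available; the classifier also reports whether any
age differs significantly from the youngest (the "significant age
effect" notion).  Classification needs a span of at least 3 ages.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not US
demography: maternal age is a rounded truncated normal (default mean 29,
sd 6 on 13–52), paternal age is maternal age plus a rounded N(2.5, 4)
gap clipped to 13–70 (parent-age correlation ≈ 0.83), father missingness
is 12% at baseline and 72% below maternal age 15, DS/CD risks are
logistic in maternal age with a knot at 30 (baselines 8e-4 / 4e-4,
slopes +0.25 / +0.20 log-odds per year above the knot), and each
outcome's risk is additive on the logit scale in a maternal curve, a
paternal curve and DS/CD log-odds multipliers.  Curves are piecewise
quadratics about a trough (or explicit per-age tables); the default
outcome baselines and endpoint ORs echo the magnitudes of the published
national analysis (troughs near maternal 30 / paternal 35) without
claiming its effect sizes.  When the father is missing, the paternal
curve is evaluated at maternal age + mean gap — such records are deleted
by the filter anyway, so the convention never leaks into fitted tables.
The generator records the exact OR curves and the planted filter
violations, counted from its own arrays with the same precedence as the
filter, so audit equality is an exact cross-implementation check.

What the generator does **not** emulate: secular trends, parity,
plurality, joint birthweight–gestation structure (an optional independent
add-on exists only to exercise the SGA derivation), non-additive
age-by-age interaction, and real US age-distribution tails.  Passing
recovery tests therefore shows the estimator recovers the model it
assumes under realistic sample sizes and missingness — not that the
published effect estimates are correct.

## Verification experiments and their problem sizes

* **Oracle agreement**: ≤4-age fixtures, `sd` bracketed to ±1% around the
  oracle's fixed value; 2×50,000 iterations thinned by 10; agreement
  within 0.02 on every posterior mean.
* **Prior recovery**: all-zero tables, 35 ages; 2,000 thinned draws must
  pass a KS test against Uniform(0,10) at α = 0.01.
* **Parameter recovery / confounding control**: 20 cohorts of 100,000
  births with distinct maternal (endpoint ORs 1.5/2.0, trough 30) and
  paternal (1.6/2.2, trough 35) quadratic curves, OR_DS = 5, OR_CD = 10.
  The joint model is fitted on the DS/CD-negative subset (2 chains,
  2,000 burn-in, 20,000 iterations thinned by 10) and supplies both
  adjusted curves; DS/CD depend only on maternal age in the generator, so
  the restricted fit is unbiased for the paternal curve too.  Curves are
  compared to truth standardized at the trough ages (30/35): the age-15
  reference holds ~1% of births and its noise would correlate every
  (sim, age) comparison.  Required: 95% CI coverage ≥ 90% of (sim, age)
  pairs, and the univariate total maternal curve (confounded by the
  correlated paternal effect and DS/CD mediation) must err more than the
  adjusted curve in ≥ 16/20 cohorts.  The paternal confounder is set
  comparable to the maternal effect so that the confounding signal is
  visible above posterior noise at this cohort size.
* **Shape recovery**: U, J, increasing and flat single-outcome scenarios,
  200,000 births, maternal spread widened to (30, 8.5) so the span's
  extreme ages — which the decision rules compare — carry real case
  counts; ≥ 9/10 seeded replicates must classify correctly.
* **Smoothing gain**: on a smooth-truth cohort the RW-prior 95% band must
  be narrower than the independent per-age Beta band at ≥ 80% of ages.

`scripts/acceptance.py` re-runs the same experiments at reduced size
(8 recovery cohorts, 3 seeds per shape) and writes the measured
quantities as JSON.

## Numerical notes and limitations

* Likelihood evaluations skip zero-birth cells (they contribute exactly
  zero); log(1+e^x) is computed with `logaddexp` for stability.
* Percentile-based summaries use linear interpolation between order
  statistics, so reciprocal identities such as `OR(a,b)·OR(b,a) = 1` hold
  exactly draw-wise and to interpolation accuracy in the summaries.
* The classifier inherits the usual selection caveat: the trough is
  estimated from the same posterior it is then compared against; RW
  shrinkage keeps the induced optimism small in the flat scenario, which
  the recovery test checks.
* Posterior tails at data-free ages (paternal 60–65 in realistic
  cohorts) are prior-dominated: wide intervals, honest but uninformative.
* The beta-binomial exposure ORs are crude (no age adjustment) by
  design, mirroring the descriptive table they reproduce.
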