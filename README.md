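# parage

Bayesian estimation of how maternal and paternal age, at one-year
resolution, shape the risk of ten neonatal morbidity and mortality (NMM)
outcomes — preterm and very preterm birth, small-for-gestational-age
(SGA), low Apgar score, NICU admission, treatment with antibiotics,
surfactant or prolonged ventilation, seizures, and in-hospital death —
and how much of the maternal-age risk is carried by Down syndrome (DS)
and other chromosomal disorders (CD).

It is written for perinatal epidemiologists who have birth-record data
(e.g. mapped from national natality files into the package's simple CSV
schema) and want nonparametric, smoothed age-risk curves instead of
10-year age bins, plus a tested synthetic-cohort generator to validate
the whole pipeline when the real microdata cannot be shared.

## The model

For each outcome k, case counts are cross-tabulated by single year of
parent age (35 maternal levels 15–49, 51 paternal levels 15–65, or the
full 35×51 grid) and modelled as

    Y_i ~ Binomial(n_i, μ_i),    logit(μ_i) = α + maternal_i [+ paternal_j]

with a flat prior on α and a first-order random-walk (intrinsic CAR)
prior on each per-age effect vector — adjacent ages shrink toward each
other with a scale sd ~ Uniform(0, 10):

    p(effect | sd) ∝ sd^-(K-1) exp( -Σ_a (effect_{a+1} - effect_a)² / 2sd² )

Posteriors come from an adaptive Metropolis-within-Gibbs sampler (2
chains, 5,000 burn-in, 200,000 iterations keeping every 100th, by
default), verified against a dense-quadrature oracle on small fixtures.
Odds ratios are standardized draw-wise to a reference age (15 by
convention, or the lowest-risk ages 30/35 for tabular contrasts), DS/CD
exposure ORs use exact Beta posteriors, and each fitted curve is
classified as U-shaped, J-shaped, increasing, decreasing or flat from
posterior contrasts of the extreme ages against the trough.  The
total/adjusted preset pair separates each parent's crude effect from the
effect adjusted for the other parent's (highly correlated) age and, for
mothers, for DS/CD mediation.  See `docs/methods.md` for the full
account.

## A worked example

```python
import parage as pg

# a synthetic study-like cohort with known ground truth
cfg = pg.recovery_config(n_births=100_000, seed=7)
cohort, truth = pg.simulate_cohort(cfg)
filtered, report = pg.filter_cohort(cohort)
print(report.as_dict())

# adjusted model: DS/CD-negative neonates, joint maternal x paternal fit
sub = pg.restrict_ds_cd_negative(filtered)
table = pg.tabulate_joint(sub, outcomes=("preterm",))
model = pg.AgeRiskModel.from_table(table, "preterm")
res = model.fit(pg.MCMCConfig(n_chains=2, burn_in=2000, iterations=20000, thin=10, seed=11))

print(res.pairwise_or(49, 30, axis="maternal"))   # oldest vs lowest-risk age
print(res.pairwise_or(15, 30, axis="maternal"))
print(res.classify_shape(axis="maternal").label)
print("truth OR(49 vs 30) =", round(float(
    pg.true_or_curve(cfg, "preterm", "maternal", 30).median[49 - 15]), 3))
```

prints

```
{'n_input': 100000, 'n_mother_under_min': 811, 'n_mother_over_max': 32,
 'n_father_out_of_range_or_missing': 12556, 'n_deleted_for_parent_age': 13399,
 'n_deleted_for_missing_outcome': 0, 'n_retained': 86601}
1.46 (1.07, 2.12)
1.39 (1.12, 1.76)
U
truth OR(49 vs 30) = 2.0
```

Reading: of 100,000 simulated births, 13,399 were deleted for missing or
out-of-range parent ages (the audit categories match the generator's
planted counts exactly).  On the DS/CD-negative subset the adjusted
maternal curve puts the odds of preterm birth at age 49 at 1.46 times
the age-30 minimum, with a wide 95% credible interval (1.07–2.12) that
covers the generator's true value of 2.0 — age 49 holds only ~100 births
at this cohort size, so the random-walk prior shrinks its point estimate
toward the better-measured neighbouring ages while the interval stays
honest.  Age 15 carries 1.39 (1.12–1.76) times the age-30 odds.  Both
ends rise significantly above the trough but the old-vs-young contrast
is not resolved at this sample size, so the curve is classified U-shaped
rather than J (at the study's ~13M births the same contrast is sharp;
the recovery tests show the classifier separating U from J reliably when
the extreme ages carry adequate counts).

The same pipeline runs from the shell:

```sh
parage all --config examples/demo.yaml --out-dir scratch/demo
```

which simulates, filters, tabulates, fits the DS/CD exposure ORs and all
four model presets for every outcome, and writes per-outcome draws,
curve CSV/JSON reports with classifications, and convergence summaries.

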