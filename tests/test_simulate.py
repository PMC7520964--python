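"""Synthetic-cohort generator: determinism, rates, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from parage import (
    ExposureRisk,
    OutcomeSpec,
    QuadraticCurve,
    SimConfig,
    TableCurve,
    curve_from_endpoints,
    filter_cohort,
    simulate_cohort,
    tabulate_binary,
    true_or_curve,
)


def null_config(n=50000, seed=0, baseline=0.10):
    spec = OutcomeSpec(baseline=baseline)
    return SimConfig(
        n_births=n,
        seed=seed,
        father_missing_base=0.0,
        father_missing_young=0.0,
        ds=ExposureRisk(baseline=1e-9),
        cd=ExposureRisk(baseline=1e-9),
        outcomes=(("nicu", spec),),
    )


def test_same_config_gives_identical_cohort():
    a, _ = simulate_cohort(null_config(n=5000, seed=3))
    b, _ = simulate_cohort(null_config(n=5000, seed=3))
    pd.testing.assert_frame_equal(a.df, b.df)


def test_different_seed_changes_cohort():
    a, _ = simulate_cohort(null_config(n=5000, seed=3))
    b, _ = simulate_cohort(null_config(n=5000, seed=4))
    assert not a.df.equals(b.df)


def test_null_configuration_hits_baseline_rate():
    cohort, _ = simulate_cohort(null_config(n=50000, seed=1))
    rate = cohort.df["nicu"].astype(bool).mean()
    assert abs(rate - 0.10) < 0.005


def test_configured_ds_odds_ratio_recovered_from_cross_tab():
    spec = OutcomeSpec(baseline=0.05, or_ds=5.0)
    cfg = SimConfig(
        n_births=500_000,
        seed=2,
        ds=ExposureRisk(baseline=0.01, knot=30, slope=0.15),
        outcomes=(("death", spec),),
    )
    cohort, truth = simulate_cohort(cfg)
    t = tabulate_binary(cohort, "ds", outcomes=("death",))
    c = t.counts["death"]
    sample_or = (c.cases_exposed / (c.births_exposed - c.cases_exposed)) / (
        c.cases_unexposed / (c.births_unexposed - c.cases_unexposed)
    )
    assert truth.ds_or["death"] == 5.0
    assert abs(sample_or - 5.0) / 5.0 < 0.10


def test_planted_violations_match_filter_report(sim_default):
    assert sim_default["truth"].planted == sim_default["report"].as_dict()


def test_father_missingness_concentrated_at_young_mothers():
    cfg = SimConfig(n_births=80000, seed=5, outcomes=(("nicu", OutcomeSpec(0.1)),))
    cohort, _ = simulate_cohort(cfg)
    df = cohort.df
    young = df["mage"] < 15
    miss_young = df.loc[young, "page"].isna().mean()
    miss_rest = df.loc[~young, "page"].isna().mean()
    assert miss_young > 0.6
    assert 0.09 < miss_rest < 0.15


def test_parent_age_correlation_matches_mc_oracle():
    cfg = null_config(n=100_000, seed=6)
    cohort, _ = simulate_cohort(cfg)
    df = cohort.df.dropna(subset=["page"])
    emp = np.corrcoef(df["mage"].astype(float), df["page"].astype(float))[0, 1]
    # straightforward large-sample oracle built the same mechanistic way
    rng = np.random.default_rng(999)
    m = np.clip(np.round(rng.normal(29, 6, size=400_000)), 13, 52)
    p = np.clip(np.round(m + rng.normal(2.5, 4, size=400_000)), 13, 70)
    oracle = np.corrcoef(m, p)[0, 1]
    assert abs(emp - oracle) < 0.05


def test_per_age_rates_track_configured_curve():
    curve = curve_from_endpoints(30, 15, 1.5, 49, 2.0)
    spec = OutcomeSpec(baseline=0.10, maternal=curve)
    cfg = SimConfig(
        n_births=200_000, seed=7,
        father_missing_base=0.0, father_missing_young=0.0,
        ds=ExposureRisk(1e-9), cd=ExposureRisk(1e-9),
        outcomes=(("preterm", spec),),
    )
    cohort, _ = simulate_cohort(cfg)
    df = cohort.df
    base_eta = np.log(0.1 / 0.9)
    for age in (20, 25, 30, 35, 40):
        grp = df[df["mage"] == age]
        n = len(grp)
        if n < 1000:
            continue
        p_true = 1 / (1 + np.exp(-(base_eta + float(curve(age)))))
        emp = grp["preterm"].astype(bool).mean()
        assert abs(emp - p_true) < 4 * np.sqrt(p_true * (1 - p_true) / n)


class TestTrueOrCurve:
    def test_reference_is_exactly_one(self):
        cfg = SimConfig(outcomes=(("preterm", OutcomeSpec(0.1, QuadraticCurve(30, 1e-3))),))
        c = true_or_curve(cfg, "preterm", "maternal", reference_age=15)
        assert c.median[0] == 1.0

    def test_quadratic_truth_symmetric_about_trough(self):
        cfg = SimConfig(outcomes=(("preterm", OutcomeSpec(0.1, QuadraticCurve(30, 2e-3))),))
        c = true_or_curve(cfg, "preterm", "maternal", reference_age=30)
        i = {a: int(a - 15) for a in (25, 35, 20, 40)}
        assert c.median[i[25]] == pytest.approx(c.median[i[35]], rel=1e-12)
        assert c.median[i[20]] == pytest.approx(c.median[i[40]], rel=1e-12)

    def test_table_and_quadratic_encodings_agree(self):
        q = QuadraticCurve(30, 1.5e-3)
        ages = tuple(range(13, 53))
        t = TableCurve(ages, tuple(float(q(a)) for a in ages))
        cq = true_or_curve(SimConfig(outcomes=(("sga", OutcomeSpec(0.1, q)),)), "sga", "maternal")
        ct = true_or_curve(SimConfig(outcomes=(("sga", OutcomeSpec(0.1, t)),)), "sga", "maternal")
        assert np.allclose(cq.median, ct.median, rtol=1e-10)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        SimConfig(father_missing_base=1.4)
    with pytest.raises(ValueError):
        SimConfig(outcomes=(("nicu", OutcomeSpec(baseline=0.0)),))
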