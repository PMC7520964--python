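"""RW1 prior, binomial-logit likelihood and sampler invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parage import (
    MCMCConfig,
    ModelSpec,
    binomial_logit_loglik,
    rw_log_prior,
    sample_posterior,
)


class TestRwLogPrior:
    def test_constant_vector_has_zero_increment_sum(self):
        assert rw_log_prior(np.zeros(7), sd=1.0) == 0.0
        assert rw_log_prior(np.full(7, 3.2), sd=1.0) == 0.0

    def test_hand_arithmetic_on_increments(self):
        # increments 1 and 2 -> -(1 + 4)/2 = -2.5 at sd 1
        assert rw_log_prior([0.0, 1.0, 3.0], sd=1.0) == pytest.approx(-2.5)

    def test_doubling_sd_costs_km1_log2_at_zero_increments(self):
        K = 9
        d = rw_log_prior(np.zeros(K), 1.0) - rw_log_prior(np.zeros(K), 2.0)
        assert d == pytest.approx((K - 1) * np.log(2.0))

    @pytest.mark.parametrize("sd", [0.0, -1.0, 10.0, 11.0])
    def test_out_of_bounds_sd_is_minus_inf(self, sd):
        assert rw_log_prior([0.0, 1.0], sd) == -np.inf

    @given(shift=st.floats(-5, 5), sd=st.floats(0.1, 9.9))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_level_shift(self, shift, sd):
        e = np.array([0.3, -0.2, 0.8, 0.1])
        assert rw_log_prior(e + shift, sd) == pytest.approx(rw_log_prior(e, sd), abs=1e-9)


class TestBinomialLogitLoglik:
    def test_half_probability_closed_form(self):
        ll = binomial_logit_loglik(np.array([1]), np.array([2]), 0.0, [np.zeros(1)])
        assert ll == pytest.approx(2 * np.log(0.5))

    def test_empty_data_is_exactly_zero(self):
        assert binomial_logit_loglik(np.zeros(5), np.zeros(5), 1.7, [np.ones(5)]) == 0.0

    def test_cases_exceeding_births_rejected(self):
        with pytest.raises(ValueError):
            binomial_logit_loglik(np.array([3]), np.array([2]), 0.0, [np.zeros(1)])

    def test_matches_record_level_bernoulli_oracle(self):
        rng = np.random.default_rng(7)
        ages = rng.integers(15, 20, size=50)
        flags = rng.random(50) < 0.3
        alpha, effects = -0.7, np.array([0.1, -0.2, 0.4, 0.0, -0.3])
        # table form
        K = 5
        Y = np.bincount(ages - 15, weights=flags, minlength=K)
        n = np.bincount(ages - 15, minlength=K)
        ll_table = binomial_logit_loglik(Y, n, alpha, [effects])
        # per-record Bernoulli oracle
        eta = alpha + effects[ages - 15]
        p = 1 / (1 + np.exp(-eta))
        ll_rec = np.sum(np.where(flags, np.log(p), np.log(1 - p)))
        assert ll_table == pytest.approx(ll_rec, rel=1e-12)

    def test_invariant_to_alpha_effect_tradeoff(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 10, size=(4, 6))
        n = Y + rng.integers(0, 20, size=(4, 6))
        em, ep = rng.normal(size=4), rng.normal(size=6)
        base = binomial_logit_loglik(Y, n, 0.5, [em, ep])
        c = 1.234
        shifted = binomial_logit_loglik(Y, n, 0.5 + c, [em - c / 2, ep - c / 2])
        assert shifted == pytest.approx(base, abs=1e-9)


class TestSampler:
    def _spec(self, lo=20, hi=22, sd_bounds=(0.0, 10.0)):
        return ModelSpec(
            axes=("maternal",),
            spans=(("maternal", (lo, hi)), ("paternal", (15, 65))),
            sd_bounds=sd_bounds,
        )

    def test_seed_determinism_bit_identical(self):
        cfg = MCMCConfig(n_chains=2, burn_in=200, iterations=1000, thin=5, seed=77)
        a = sample_posterior(self._spec(), np.array([1, 5, 1]), np.array([10, 10, 10]), cfg)
        b = sample_posterior(self._spec(), np.array([1, 5, 1]), np.array([10, 10, 10]), cfg)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.effects["maternal"], b.effects["maternal"])
        assert np.array_equal(a.sd["maternal"], b.sd["maternal"])

    def test_every_stored_draw_sums_to_zero(self):
        cfg = MCMCConfig(n_chains=2, burn_in=200, iterations=2000, thin=5, seed=5)
        d = sample_posterior(self._spec(), np.array([2, 8, 3]), np.array([20, 20, 20]), cfg)
        sums = d.effects["maternal"].sum(axis=-1)
        assert np.max(np.abs(sums)) < 1e-10

    def test_no_data_sd_posterior_spans_prior(self):
        spec = self._spec(15, 24)
        cfg = MCMCConfig(n_chains=2, burn_in=500, iterations=10000, thin=10, seed=11)
        d = sample_posterior(spec, np.zeros(10, int), np.zeros(10, int), cfg)
        sd = d.pooled_sd("maternal")
        assert abs(sd.mean() - 5.0) < 0.7  # Uniform(0,10) mean, MC slack
        assert sd.min() > 0.0 and sd.max() < 10.0

    def test_single_age_span_recovers_empirical_logit(self):
        spec = ModelSpec(axes=("maternal",), spans=(("maternal", (30, 30)), ("paternal", (15, 65))))
        cfg = MCMCConfig(n_chains=2, burn_in=1000, iterations=10000, thin=10, seed=3)
        d = sample_posterior(spec, np.array([500]), np.array([1000]), cfg)
        logit = d.pooled_alpha() + d.pooled_effects("maternal")[:, 0]
        assert abs(logit.mean()) < 0.05

    def test_mismatched_span_rejected(self):
        cfg = MCMCConfig(n_chains=1, burn_in=10, iterations=10, thin=1, seed=0)
        with pytest.raises(ValueError, match="shape"):
            sample_posterior(self._spec(), np.array([1, 2]), np.array([5, 5]), cfg)

    def test_acceptance_rates_near_target_after_adaptation(self):
        cfg = MCMCConfig(n_chains=1, burn_in=2000, iterations=4000, thin=4, seed=21)
        d = sample_posterior(self._spec(15, 30), np.full(16, 30), np.full(16, 100), cfg)
        rate = d.acceptance[0]["effects[maternal]"]
        assert 0.2 < rate < 0.7
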