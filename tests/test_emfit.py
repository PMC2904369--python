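"""Mixture likelihood, EM estimation and likelihood-ratio testing."""

import numpy as np
import pytest
from scipy import stats

from iqtlmap.design import NON_MEAN_EFFECTS, effects_to_means
from iqtlmap.emfit import (STANDARD_TESTS, CrossDataset, em_fit,
                           likelihood_ratio_test, mixture_loglik,
                           standard_test_constraints, validate_constraints)
from iqtlmap.simulate import SimulationScenario, scenario_effects, simulate_cross


def _degenerate_priors(config):
    pri = np.zeros((len(config), 4))
    pri[np.arange(len(config)), config] = 1.0
    return pri


class TestMixtureLoglik:
    def test_degenerate_single_observation(self):
        means = np.zeros((4, 4))
        pri = np.zeros((1, 4))
        pri[0, 2] = 1.0
        ll = mixture_loglik(np.array([0.0]), np.array([1]), pri, means, 1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_collapses_to_single_normal(self, rng):
        y = rng.normal(2.0, 1.5, 200)
        fam = rng.integers(0, 4, 200)
        pri = np.full((200, 4), 0.25)
        means = np.full((4, 4), 2.0)
        expect = stats.norm.logpdf(y, 2.0, 1.5).sum()
        assert mixture_loglik(y, fam, pri, means, 1.5 ** 2) == pytest.approx(expect)

    def test_matches_direct_summation_oracle(self, rng):
        y = rng.normal(0, 1, 50)
        fam = rng.integers(0, 4, 50)
        pri = rng.dirichlet(np.ones(4), 50)
        means = rng.normal(0, 1, (4, 4))
        s2 = 0.7
        brute = sum(
            np.log(sum(pri[i, k] * stats.norm.pdf(y[i], means[fam[i], k], np.sqrt(s2))
                       for k in range(4)))
            for i in range(50))
        assert mixture_loglik(y, fam, pri, means, s2) == pytest.approx(brute)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            mixture_loglik(np.zeros(1), np.zeros(1, int), np.full((1, 4), .25),
                           np.zeros((4, 4)), 0.0)


class TestConstraints:
    def test_standard_test_sizes(self):
        assert len(standard_test_constraints(1)) == 13
        assert len(standard_test_constraints(2)) == 3
        assert len(standard_test_constraints(3)) == 10
        for t in (4, 5, 6):
            assert len(standard_test_constraints(t)) == 3
        assert standard_test_constraints(6) == {"i1mp_a", "i1mp_d", "i1mp_i2"}

    def test_hierarchy_structure(self):
        assert STANDARD_TESTS[1] == STANDARD_TESTS[2] | STANDARD_TESTS[3]
        assert STANDARD_TESTS[4] | STANDARD_TESTS[5] | STANDARD_TESTS[6] < STANDARD_TESTS[3]

    def test_single_effect_and_errors(self):
        assert standard_test_constraints("i2") == {"i2"}
        with pytest.raises(ValueError):
            standard_test_constraints(7)
        with pytest.raises(ValueError):
            standard_test_constraints("bogus")
        with pytest.raises(ValueError):
            validate_constraints({"mu"})


class TestEMFit:
    def test_degenerate_priors_reach_closed_form(self, small_cross):
        """With configurations observed, EM equals per-cell means / pooled MLE var."""
        data = small_cross.data
        pri = _degenerate_priors(small_cross.true_config)
        fit = em_fit(data, pri, ())
        cell = data.family * 4 + small_cross.true_config
        mu_hat = np.array([data.phenotype[cell == c].mean() for c in range(16)])
        s2_hat = np.mean((data.phenotype - mu_hat[cell]) ** 2)
        assert np.allclose(fit.means.ravel(), mu_hat, atol=1e-6)
        assert fit.sigma2 == pytest.approx(s2_hat, rel=1e-6)

    def test_all_effects_constrained_is_single_normal(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        fit = em_fit(data, pri, NON_MEAN_EFFECTS)
        assert fit.effects.mu == pytest.approx(data.phenotype.mean())
        assert fit.sigma2 == pytest.approx(np.var(data.phenotype))
        assert fit.n_free_effects == 1

    def test_loglik_monotone_along_iterations(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        for cons in ((), standard_test_constraints(1), standard_test_constraints(3)):
            fit = em_fit(data, pri, cons)
            diffs = np.diff(fit.trace)
            assert np.all(diffs >= -1e-6), f"EM decreased logL under {cons}"

    def test_constrained_loglik_never_exceeds_full(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        full = em_fit(data, pri, ())
        for t in (1, 2, 3):
            null = em_fit(data, pri, standard_test_constraints(t))
            assert null.loglik <= full.loglik + 1e-6

    def test_constrained_effects_exactly_zero(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        fit = em_fit(data, pri, standard_test_constraints(1))
        for name in standard_test_constraints(1):
            assert getattr(fit.effects, name) == 0.0

    def test_estimates_approach_truth_with_size(self):
        """Bias shrinks and identifiable effects are recovered as n grows."""
        truth = scenario_effects("I")
        errs = {}
        for n in (100, 600):
            per_seed = []
            for seed in range(5):
                sc = SimulationScenario.reference("I", n, h2=0.4)
                sim = simulate_cross(sc, seed=seed)
                fit = em_fit(sim.data, _degenerate_priors(sim.true_config), ())
                per_seed.append(np.abs(np.array([
                    fit.effects.a - truth.a, fit.effects.d - truth.d,
                    fit.effects.i1m - truth.i1m])).mean())
            errs[n] = np.mean(per_seed)
        assert errs[600] < errs[100]
        assert errs[600] < 0.05

    def test_empty_family_flagged(self):
        sc = SimulationScenario.reference("I", 40, h2=0.4)
        sim = simulate_cross(sc, seed=2)
        data = sim.data
        keep = data.family != 3
        sub = CrossDataset(marker_map=data.marker_map, family=data.family[keep],
                           phenotype=data.phenotype[keep],
                           genotypes=data.genotypes.loc[keep].reset_index(drop=True))
        with pytest.raises(ValueError, match="empty family"):
            em_fit(sub, sub.priors_at("1", 35.0), ())


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        full = em_fit(data, pri, ())
        null = em_fit(data, pri, standard_test_constraints(2))
        r = likelihood_ratio_test(null, full)
        assert r.df == 3
        assert r.lr >= 0.0
        same = likelihood_ratio_test(null, null.__class__(**{**null.__dict__,
                                                             "constraints": frozenset()}))
        assert same.lr == 0.0 and same.pvalue == 1.0

    def test_df_bookkeeping(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        full = em_fit(data, pri, ())
        expected_df = {1: 13, 2: 3, 3: 10, 4: 3, 5: 3, 6: 3}
        for t, df in expected_df.items():
            null = em_fit(data, pri, standard_test_constraints(t))
            assert likelihood_ratio_test(null, full).df == df

    def test_non_nested_rejected(self, small_cross):
        data = small_cross.data
        pri = data.priors_at("1", 35.0)
        f2 = em_fit(data, pri, standard_test_constraints(2))
        f4 = em_fit(data, pri, standard_test_constraints(4))
        with pytest.raises(ValueError):
            likelihood_ratio_test(f2, f4)

    def test_null_lr_matches_chisq_quantiles(self):
        """Test 2's LR under a no-imprinting truth follows chi-square(3)."""
        reps = 120
        lrs = []
        ss = np.random.SeedSequence(314).spawn(reps)
        for s in ss:
            rng = np.random.default_rng(s)
            sc = SimulationScenario.reference("III", 100, h2=0.4)
            sim = simulate_cross(sc, rng)
            pri = sim.data.priors_at("1", 35.0)
            full = em_fit(sim.data, pri, (), seed=rng)
            null = em_fit(sim.data, pri, standard_test_constraints(2), seed=rng)
            lrs.append(likelihood_ratio_test(null, full).lr)
        ks = stats.kstest(lrs, stats.chi2(3).cdf)
        assert ks.pvalue > 0.01
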