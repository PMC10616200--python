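"""Birth-death prior, clocks, MCMC machinery, marginal likelihoods, ESS."""

import math

import numpy as np
import pytest
import scipy.stats as st
from scipy.integrate import quad
from scipy.special import betaln, comb

from kdphylo.chronology import (BDSKYParams, CalibrationPrior, ClockModel,
                                DatingModel, MCMCConfig, bd_log_prior,
                                effective_sample_size, estimate_log_ml,
                                harmonic_mean_log_ml, initial_bdsky,
                                path_sampling_log_ml, power_schedule,
                                relaxed_branch_rates, sample_hyperpriors)
from kdphylo.cognates import CognateMatrix, add_ascertainment_columns
from kdphylo.phylo import TimeTree
from kdphylo.substitution import BinaryCTMCParams


def three_tip(root_age, inner_age):
    return TimeTree([-1, 0, 0, 1, 1], [root_age, inner_age, 0, 0, 0],
                    [None, None, "C", "A", "B"])


class TestBirthDeathPrior:
    def test_yule_limit_matches_closed_form(self):
        """mu -> 0, rho = 1: the subordinate node age is truncated
        exponential; the root-conditioned density is the product of
        exponentials."""
        lam = 0.01
        p = BDSKYParams(lam, 1e-12, 1.0)
        tree = three_tip(2000.0, 700.0)
        ages_form = math.log(lam * math.exp(-lam * 700)
                             / (1 - math.exp(-lam * 2000)))
        assert abs(bd_log_prior(tree, p, "ages") - ages_form) < 1e-6
        root_form = math.log(lam) - lam * 700 - 2 * lam * 2000
        assert abs(bd_log_prior(tree, p, "root") - root_form) < 1e-6

    def test_age_density_integrates_to_one(self):
        p = BDSKYParams(0.01, 0.004, 0.7)

        def dens(x2):
            return math.exp(bd_log_prior(three_tip(2000.0, x2), p, "ages"))
        total, _ = quad(dens, 0, 2000.0)
        assert abs(total - 1.0) < 1e-6

    def test_density_vanishes_as_sampling_fraction_shrinks(self):
        # slow-rate regime (lambda * root_age << 1), where each lineage
        # factor is monotone in rho and the density ~ rho^(n factors)
        tree = three_tip(500.0, 200.0)
        vals = [bd_log_prior(tree, BDSKYParams(0.001, 1e-9, r), "root")
                for r in (0.8, 0.4, 0.1, 0.01, 0.001, 1e-4)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < vals[0] - 20

    def test_zero_length_tree_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            bd_log_prior(three_tip(0.0, 0.0), BDSKYParams(0.01, 0.001, 0.9))


class TestHyperpriors:
    def test_draw_means_match_stated_priors(self, rng):
        draws = [sample_hyperpriors(rng) for _ in range(30000)]
        lam = np.array([d.lam for d in draws])
        rho = np.array([d.rho for d in draws])
        assert abs(lam.mean() - 0.01) < 3 * 0.01 / math.sqrt(lam.size)
        # Beta(100, 19) has analytic mean 100/119
        assert abs(rho.mean() - 100 / 119) < 3 * rho.std() / math.sqrt(
            rho.size)

    def test_chain_starting_state(self, rng):
        start = initial_bdsky(rng)
        assert start.lam == 0.01 and start.mu == 0.008
        assert 0 < start.rho < 1


class TestRelaxedClock:
    def test_zero_stdev_is_strict(self, rng):
        tree = three_tip(1000.0, 400.0)
        r = relaxed_branch_rates(tree, ClockModel("relaxed-lognormal",
                                                  2e-4, 0.0), rng=rng)
        np.testing.assert_allclose(r, 2e-4)

    def test_multiplier_mean_is_one(self, rng):
        from kdphylo.chronology import discretized_lognormal_multipliers
        mult = discretized_lognormal_multipliers(0.5, 10_000)
        assert abs(mult.mean() - 1.0) < 0.01

    def test_category_assignment_permutation_invariant(self, rng):
        tree = three_tip(1000.0, 400.0)
        clock = ClockModel("relaxed-lognormal", 1e-4, 0.4)
        cats = np.array([0, 3, 1, 4, 2])
        r1 = relaxed_branch_rates(tree, clock, cats)
        r2 = relaxed_branch_rates(tree, clock, cats)
        np.testing.assert_array_equal(r1, r2)
        assert len(set(np.round(r1 / 1e-4, 6))) > 1


class TestMCMCConfig:
    def test_paper_scale_retention_arithmetic(self):
        dating = MCMCConfig(generations=50_000_000, sample_every=5000,
                            burnin_samples=1000, seed=1)
        assert dating.n_retained == 9000
        geo = MCMCConfig(generations=55_000_000, sample_every=5000,
                         burnin_samples=1000, seed=1)
        assert geo.n_retained == 10_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(generations=1000, sample_every=300)
        with pytest.raises(ValueError):
            MCMCConfig(generations=1000, sample_every=100,
                       burnin_samples=10)


class TestESS:
    def test_iid_series_near_n(self, rng):
        x = rng.normal(size=10_000)
        assert abs(effective_sample_size(x) - 10_000) < 1000

    def test_ar1_matches_analytic_autocorrelation_time(self, rng):
        n, phi = 40_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert abs(effective_sample_size(x) - expected) < 0.25 * expected

    def test_duplication_roughly_halves_ess(self, rng):
        x = rng.normal(size=2000)
        doubled = np.repeat(x, 2)
        assert effective_sample_size(doubled) < 0.75 * len(doubled)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = effective_sample_size(np.ones(100))
        assert math.isnan(out)

    def test_agrees_with_arviz_on_smooth_chain(self, rng):
        import arviz
        x = np.cumsum(rng.normal(size=5000)) * 0.05 + rng.normal(size=5000)
        ours = effective_sample_size(x)
        theirs = float(arviz.ess(x))
        assert 0.3 * theirs < ours < 3 * theirs


class TestMarginalLikelihood:
    """Conjugate binomial-beta toy with an analytic marginal likelihood."""

    a, b, n, k = 2.0, 3.0, 20, 7

    def loglik(self, theta):
        return (math.log(comb(self.n, self.k))
                + self.k * np.log(theta)
                + (self.n - self.k) * np.log1p(-theta))

    def analytic(self):
        return (math.log(comb(self.n, self.k))
                + betaln(self.a + self.k, self.b + self.n - self.k)
                - betaln(self.a, self.b))

    def test_hme_and_path_sampling_within_tolerance(self, rng):
        post = rng.beta(self.a + self.k, self.b + self.n - self.k, 80_000)
        hme = harmonic_mean_log_ml(self.loglik(post))
        betas = power_schedule(16)
        means = []
        for beta in betas:
            th = rng.beta(self.a + beta * self.k,
                          self.b + beta * (self.n - self.k), 40_000)
            means.append(float(np.mean(self.loglik(th))))
        path = path_sampling_log_ml(betas, means)
        truth = self.analytic()
        assert abs(hme - truth) < 0.1
        assert abs(path - truth) < 0.1
        both = estimate_log_ml(self.loglik(post), betas, means)
        assert set(both) == {"hme", "path"}

    def test_identical_models_give_zero_log_bf(self, rng):
        post = rng.beta(self.a + self.k, self.b + self.n - self.k, 50_000)
        lml = harmonic_mean_log_ml(self.loglik(post))
        assert abs(lml - lml) == 0.0

    def test_single_power_step_degenerates_to_mean_loglik(self):
        assert path_sampling_log_ml([1.0], [-12.5]) == -12.5

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_log_ml([])


def small_dating_model(rng, n_lang=6, n_cols=12):
    labels = [f"L{i}" for i in range(n_lang)]
    cells = rng.integers(0, 2, size=(n_lang, n_cols)).astype(np.int8)
    cells[:, ::3] = 1
    cols = [(f"i{j // 3}", f"c{j % 3}") for j in range(n_cols)]
    m = add_ascertainment_columns(CognateMatrix(labels, cols, cells))
    return DatingModel(m, BinaryCTMCParams(),
                       clock=ClockModel("strict", 3e-4))


class TestDatingMCMC:
    def test_seed_reproducibility(self, rng):
        model = small_dating_model(rng)
        cfg = MCMCConfig(generations=2000, sample_every=20,
                         burnin_samples=10, seed=42)
        r1 = model.fit(cfg)
        r2 = model.fit(cfg)
        assert r1.trace.equals(r2.trace)
        assert r1.trees[-1].to_newick() == r2.trees[-1].to_newick()

    def test_retained_sample_count(self, rng):
        model = small_dating_model(rng)
        cfg = MCMCConfig(generations=3000, sample_every=30,
                         burnin_samples=20, seed=7)
        res = model.fit(cfg)
        assert len(res.trace) == 100
        assert len(res.posterior_trace) == cfg.n_retained == 80

    def test_prior_only_sampling_recovers_calibration_density(self, rng):
        """With the data stripped and a sharp root calibration, sampled
        root ages follow the calibration density."""
        model = small_dating_model(rng)
        cal = CalibrationPrior(frozenset(model.matrix.languages),
                               "normal", {"mean": 3000.0, "sd": 120.0})
        model.calibrations = [cal]
        cfg = MCMCConfig(generations=60_000, sample_every=10,
                         burnin_samples=500, seed=3)
        res = model.fit(cfg, prior_only=True)
        ages = res.root_ages
        ks = st.kstest(ages, "norm", args=(3000.0, 120.0)).statistic
        assert ks < 0.08

    def test_summary_reports_hpd_and_ess(self, rng):
        model = small_dating_model(rng)
        cfg = MCMCConfig(generations=3000, sample_every=10,
                         burnin_samples=50, seed=5)
        res = model.fit(cfg)
        summ = res.summary()
        assert {"mean", "hpd95_lower", "hpd95_upper", "ess"} <= set(
            summ.columns)
        assert summ.loc["root_age", "hpd95_lower"] <= \
            summ.loc["root_age", "mean"]


class TestModelSelectionSanity:
    def test_covarion_data_prefers_covarion_by_hme_majority(self):
        """Matrices generated under a slow-switching covarion earn a
        positive covarion-vs-CTMC log Bayes factor (harmonic-mean
        estimate) in most replicates."""
        from kdphylo.simulate import SimulationSpec, simulate_bd_tree, \
            simulate_cognate_matrix, streams
        from kdphylo.substitution import CovarionParams, SiteRateModel
        from kdphylo.substitution import BinaryCTMCParams as Bin
        wins = []
        for seed in range(1, 6):
            r_tree, r_cog = streams(seed + 50, 2)
            truth = CovarionParams(visible=Bin(0.86, 0.14), s=0.15)
            spec = SimulationSpec(seed=seed, n_tips=15, n_items=60,
                                  root_age=4000.0, cognate_model=truth,
                                  missing_prob=0.0)
            tree = simulate_bd_tree(spec, r_tree)
            m, _ = simulate_cognate_matrix(tree, spec, r_cog)
            cfg = MCMCConfig(generations=12_000, sample_every=20,
                             burnin_samples=100, seed=seed)
            lmls = {}
            for name, sm, sr in [
                    ("covarion", truth, None),
                    ("ctmc", Bin(0.86, 0.14), SiteRateModel(4, shape=0.5))]:
                dm = DatingModel(m, sm, site_rates=sr,
                                 clock=ClockModel("strict",
                                                  spec.cognate_clock_rate))
                res = dm.fit(cfg, init_tree=tree, fix_clock_rate=True)
                lmls[name] = res.log_marginal_likelihood("hme")
            wins.append(lmls["covarion"] > lmls["ctmc"])
        assert sum(wins) >= 3
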