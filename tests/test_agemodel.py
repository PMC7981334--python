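"""MAP location-scale age model: oracles, recovery, invariances."""

import numpy as np
import pytest
from scipy import optimize

from fcaging import synthetic
from fcaging.agemodel import (
    AgeModelPriors,
    consistency_correlation,
    fit_all,
    fit_map,
    neg_log_posterior,
    sd_at_age,
)
from fcaging.synthetic import CohortSpec, EffectConfig, make_cohort, sample_edge_truth


def _two_group_ages(rng, n=60):
    return np.concatenate(
        [rng.normal(24.2, 3.4, n // 2), rng.normal(70.8, 2.7, n - n // 2)]
    )


def _ols(y, x):
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta[0], beta[1], float(np.sqrt(np.mean(resid**2)))


class TestNegLogPosterior:
    def test_homoscedastic_case_minimized_by_ols(self, rng):
        ages = _two_group_ages(rng)
        x = ages - 20
        y = 0.2 - 0.003 * x + rng.normal(0, 0.1, 60)
        a0, b0, sd = _ols(y, x)
        flat = AgeModelPriors.flat()
        best = neg_log_posterior([a0, b0, np.log(sd), 0, 0], y, ages, None, flat)
        for da, db in [(0.01, 0), (-0.01, 0), (0, 0.001), (0, -0.001)]:
            other = neg_log_posterior(
                [a0 + da, b0 + db, np.log(sd), 0, 0], y, ages, None, flat
            )
            assert other > best

    def test_equals_gaussian_nll_closed_form(self, rng):
        ages = _two_group_ages(rng, 20)
        x = ages - 20
        y = rng.normal(size=20)
        sigma = 0.3
        got = neg_log_posterior([0.1, 0.0, np.log(sigma), 0, 0], y, ages, None,
                                AgeModelPriors.flat())
        expected = 20 * np.log(sigma) + np.sum((y - 0.1) ** 2) / (2 * sigma**2)
        assert np.isclose(got, expected)

    def test_priors_add_quadratic_penalty(self, rng):
        ages = _two_group_ages(rng, 20)
        y = rng.normal(size=20)
        params = [0.5, 0.01, -1.0, 0.002, 0.1]
        flat = neg_log_posterior(params, y, ages, None, AgeModelPriors.flat())
        with_prior = neg_log_posterior(params, y, ages, None, AgeModelPriors())
        penalty = sum(
            0.5 * p**2 / s**2
            for p, s in zip(params, AgeModelPriors().scales())
        )
        assert np.isclose(with_prior - flat, penalty)

    def test_zero_params_prior_contribution_is_zero(self, rng):
        # priors symmetric around 0 attain their minimum (0 penalty) at 0
        ages = _two_group_ages(rng, 20)
        y = rng.normal(size=20)
        zero = [0.0, 0.0, 0.0, 0.0, 0.0]
        assert np.isclose(
            neg_log_posterior(zero, y, ages, None, AgeModelPriors()),
            neg_log_posterior(zero, y, ages, None, AgeModelPriors.flat()),
        )

    def test_doubling_residuals_quadruples_quadratic_term(self, rng):
        ages = _two_group_ages(rng, 20)
        y = rng.normal(size=20)
        flat = AgeModelPriors.flat()
        base = neg_log_posterior([0, 0, 0, 0, 0], y, ages, None, flat)
        doubled = neg_log_posterior([0, 0, 0, 0, 0], 2 * y, ages, None, flat)
        # log-sigma term is unchanged (sigma = 1 -> 0), quadratic term x4
        assert np.isclose(doubled - 0, 4 * base)

    def test_nonfinite_params_give_large_finite_objective(self, rng):
        ages = _two_group_ages(rng, 20)
        y = rng.normal(size=20)
        val = neg_log_posterior([np.nan, 0, 0, 0, 0], y, ages, None, None)
        assert np.isfinite(val) and val > 1e10

    def test_gradient_matches_finite_differences(self, rng):
        from fcaging.agemodel import _nlp_and_grad, _prep

        ages = _two_group_ages(rng, 30)
        y = rng.normal(size=30)
        fd = rng.uniform(0.05, 0.3, 30)
        params = np.array([0.2, -0.01, -1.5, 0.005, 0.1])
        args = _prep(y, ages, fd)
        _, grad = _nlp_and_grad(params, *args, AgeModelPriors())
        num = optimize.approx_fprime(
            params, lambda p: _nlp_and_grad(p, *args, AgeModelPriors())[0], 1e-7
        )
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-5)


class TestFitMap:
    def test_matches_ols_with_fixed_scale_params(self, rng):
        ages = _two_group_ages(rng)
        x = ages - 20
        y = 0.3 - 0.002 * x + rng.normal(0, 0.15, 60)
        fit = fit_map(
            y, ages, None, priors=AgeModelPriors.flat(),
            fixed={"beta_sigma": 0.0, "rho": 0.0},
        )
        a0, b0, sd = _ols(y, x)
        assert abs(fit.alpha_mu - a0) < 1e-6
        assert abs(fit.beta_mu - b0) < 1e-6
        assert abs(np.exp(fit.alpha_sigma) - sd) < 1e-6

    def test_large_n_recovers_true_parameters(self):
        rng = np.random.default_rng(42)
        n = 10_000
        ages = _two_group_ages(rng, n)
        x = ages - 20
        fd = rng.uniform(0.05, 0.4, n)
        true = dict(alpha_mu=0.3, beta_mu=-0.002, alpha_sigma=np.log(0.15),
                    beta_sigma=0.004, rho=0.2)
        sd = np.exp(true["alpha_sigma"] + true["beta_sigma"] * x)
        y = (true["alpha_mu"] + true["beta_mu"] * x + true["rho"] * fd
             + rng.normal(0, sd))
        fit = fit_map(y, ages, fd, priors=AgeModelPriors.flat(), n_restarts=1)
        # asymptotic SEs from standard location-scale theory
        se_bmu = sd.mean() / (np.sqrt(n) * x.std())
        se_bsg = 1 / np.sqrt(2 * n * x.var())
        se_rho = sd.mean() / (np.sqrt(n) * fd.std())
        assert abs(fit.beta_mu - true["beta_mu"]) < 3 * se_bmu
        assert abs(fit.beta_sigma - true["beta_sigma"]) < 3 * se_bsg
        assert abs(fit.rho - true["rho"]) < 3 * se_rho

    def test_age_constant_cohort_flagged_unidentifiable(self, rng):
        y = rng.normal(size=20)
        fit = fit_map(y, np.full(20, 50.0), None)
        assert not fit.identifiable
        # slopes pulled to the prior center
        assert abs(fit.beta_mu) < 1e-3 and abs(fit.beta_sigma) < 1e-3

    def test_shift_invariance_with_flat_priors(self, rng):
        ages = _two_group_ages(rng, 40)
        y = rng.normal(0, 0.2, 40)
        f0 = fit_map(y, ages, None, priors=AgeModelPriors.flat(), fixed={"rho": 0.0})
        f1 = fit_map(y + 5.0, ages, None, priors=AgeModelPriors.flat(), fixed={"rho": 0.0})
        assert abs((f1.alpha_mu - f0.alpha_mu) - 5.0) < 1e-6
        assert abs(f1.beta_mu - f0.beta_mu) < 1e-6
        assert abs(f1.beta_sigma - f0.beta_sigma) < 1e-6

    def test_objective_decreases_along_optimizer_path(self, rng):
        from fcaging.agemodel import _nlp_and_grad, _prep

        ages = _two_group_ages(rng, 60)
        x = ages - 20
        y = 0.2 - 0.002 * x + rng.normal(0, 0.15 * np.exp(0.004 * x))
        args = _prep(y, ages, None)
        priors = AgeModelPriors()
        trace = []
        optimize.minimize(
            lambda p: _nlp_and_grad(p, *args, priors),
            np.array([0.0, 0.0, -1.0, 0.0, 0.0]),
            jac=True,
            method="L-BFGS-B",
            callback=lambda p: trace.append(_nlp_and_grad(p, *args, priors)[0]),
        )
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_unknown_fixed_parameter_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_map(rng.normal(size=10), _two_group_ages(rng, 10), fixed={"gamma": 1})

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 5"):
            fit_map(np.zeros(4), np.array([20, 30, 40, 50.0]))


class TestFitAll:
    def test_sign_fraction_recovered_within_five_points(self):
        # ~70% of true beta_mu negative by construction
        cfg = EffectConfig(beta_mu_mean=-0.00119, beta_mu_sd=0.002,
                           node_coupling_mu=0.0015)
        truth = sample_edge_truth(30, cfg, seed=11)  # 435 edges
        cohort = make_cohort(CohortSpec(seed=12))
        vals = synthetic.simulate_edge_values(cohort, truth, seed=13)
        ages = np.array([r.age for r in cohort])
        fd = np.array([r.motion_trait for r in cohort])
        table = fit_all(vals, ages, fd, seed=14)
        true_frac = np.mean([e.beta_mu < 0 for e in truth])
        assert abs(table.frac_negative_beta_mu - true_frac) < 0.05

    def test_feature_order_permutes_rows(self, rng):
        ages = _two_group_ages(rng, 30)
        vals = rng.normal(size=(30, 6))
        ids = [f"e{j}" for j in range(6)]
        t1 = fit_all(vals, ages, None, feature_ids=ids, seed=0)
        perm = [3, 1, 5, 0, 2, 4]
        t2 = fit_all(vals[:, perm], ages, None, feature_ids=[ids[p] for p in perm], seed=0)
        a = t1.fits.set_index("feature").loc[[ids[p] for p in perm], "beta_mu"]
        b = t2.fits.set_index("feature")["beta_mu"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-5)

    def test_per_feature_failure_isolated(self, rng):
        ages = _two_group_ages(rng, 30)
        vals = rng.normal(size=(30, 3))
        vals[:, 1] = np.nan  # poisoned feature
        table = fit_all(vals, ages, None, seed=0)
        assert len(table.fits) == 3
        assert not table.fits.loc[1, "converged"]
        assert table.fits.loc[0, "converged"] and table.fits.loc[2, "converged"]


class TestSdAtAge:
    def test_constant_sd(self):
        from fcaging.agemodel import EdgeAgeFit

        fit = EdgeAgeFit("f", 0, 0, np.log(0.1), 0.0, 0, True, 0.0)
        assert np.isclose(sd_at_age(fit, 20), 0.1)
        assert np.isclose(sd_at_age(fit, 90), 0.1)

    def test_fifty_year_gap_factor(self):
        from fcaging.agemodel import EdgeAgeFit

        fit = EdgeAgeFit("f", 0, 0, np.log(0.1), 0.01, 0, True, 0.0)
        assert np.isclose(sd_at_age(fit, 70) / sd_at_age(fit, 20), np.exp(0.5))

    def test_negative_slope_monotone_decreasing(self):
        from fcaging.agemodel import EdgeAgeFit

        fit = EdgeAgeFit("f", 0, 0, 0.0, -0.02, 0, True, 0.0)
        sds = [sd_at_age(fit, a) for a in (20, 40, 60, 80)]
        assert all(b < a for a, b in zip(sds, sds[1:]))


class TestConsistencyCorrelation:
    def _table(self, rng, truth, cohort, noise_sd, seed):
        vals = synthetic.simulate_edge_values(cohort, truth, seed=seed)
        vals = vals + rng.normal(0, noise_sd, vals.shape)
        ages = np.array([r.age for r in cohort])
        fd = np.array([r.motion_trait for r in cohort])
        return fit_all(vals, ages, fd, seed=seed)

    def test_self_correlation_is_one(self, rng):
        ages = _two_group_ages(rng, 30)
        t = fit_all(rng.normal(size=(30, 5)), ages, None, seed=1)
        assert np.isclose(consistency_correlation(t, t, "beta_mu"), 1.0)

    def test_two_noisy_refits_positively_correlated(self, rng):
        truth = sample_edge_truth(15, seed=21)
        cohort = make_cohort(CohortSpec(seed=22))
        short = self._table(rng, truth, cohort, noise_sd=0.15, seed=23)
        short2 = self._table(rng, truth, cohort, noise_sd=0.15, seed=24)
        long1 = self._table(rng, truth, cohort, noise_sd=0.03, seed=25)
        long2 = self._table(rng, truth, cohort, noise_sd=0.03, seed=26)
        r_short = consistency_correlation(short, short2, "beta_mu")
        r_long = consistency_correlation(long1, long2, "beta_mu")
        assert r_short > 0
        # less measurement noise (longer scans) -> higher consistency
        assert r_long > r_short

    def test_feature_mismatch_rejected(self, rng):
        ages = _two_group_ages(rng, 30)
        t1 = fit_all(rng.normal(size=(30, 4)), ages, None, feature_ids=list("abcd"), seed=2)
        t2 = fit_all(rng.normal(size=(30, 4)), ages, None, feature_ids=list("abce"), seed=3)
        with pytest.raises(ValueError, match="feature sets"):
            consistency_correlation(t1, t2)

    def test_independent_tables_near_zero(self, rng):
        ages = _two_group_ages(rng, 40)
        t1 = fit_all(rng.normal(size=(40, 200)), ages, None, seed=4)
        t2 = fit_all(rng.normal(size=(40, 200)), ages, None, seed=5)
        assert abs(consistency_correlation(t1, t2, "beta_mu")) < 0.15
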