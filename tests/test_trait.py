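import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

import hmpt
from hmpt.datagen import TraitPopulationSpec, gen_trait_mpt
from hmpt.likelihood import FrequencyTable
from hmpt.mcmc import McmcSettings
from hmpt.trait import (
    PredictorSpec,
    TraitPriors,
    build_design,
    fit_trait,
    sample_prior_predictive_priors,
)


def quiet_fit(*args, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_trait(*args, **kw)


class TestBuildDesign:
    def test_continuous_standardization(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        spec = PredictorSpec.parse(["a ; x"])
        d = build_design(cov, spec, ("a", "b"))
        assert np.allclose(
            d["a"].X[:, 0], [-1.2247448, 0.0, 1.2247448]
        )
        assert d["b"].n_columns == 0
        assert d["a"].blocks[0].sd == pytest.approx(np.std([1, 2, 3]))

    def test_balanced_two_level_fixed_factor(self):
        cov = pd.DataFrame({"grp": ["lo", "lo", "hi", "hi"]})
        spec = PredictorSpec.parse(["a ; grp"], {"grp": "fixed_factor"})
        d = build_design(cov, spec, ("a",))
        col = d["a"].X[:, 0]
        assert set(col) == {1.0, -1.0}
        assert col.sum() == 0.0
        assert d["a"].n_columns == 1

    def test_three_level_random_factor(self):
        cov = pd.DataFrame({"site": ["u", "v", "w", "u", "v", "w"]})
        spec = PredictorSpec.parse(["a ; site"], {"site": "random_factor"})
        d = build_design(cov, spec, ("a",))
        assert d["a"].n_columns == 3
        assert np.allclose(d["a"].X.sum(axis=1), 1.0)  # indicator coding

    def test_zero_variance_covariate_rejected(self):
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        spec = PredictorSpec.parse(["a ; x"])
        with pytest.raises(ValueError, match="zero variance"):
            build_design(cov, spec, ("a",))


class TestPriorPredictive:
    def test_default_mu_prior_uniform_on_probability(self):
        """Standard-normal mu implies uniform Phi(mu): KS against U(0,1)."""
        from scipy import stats

        passes = 0
        for seed in range(10):
            draws = sample_prior_predictive_priors(
                TraitPriors(), S=2, n=10_000, seed=seed
            )
            p = stats.kstest(draws["prob_mean_0"], "uniform").pvalue
            passes += p > 0.01
        assert passes >= 9

    def test_precise_mu_prior_concentrates_at_half(self):
        # BUGS-style dnorm(0, 4) corresponds to sd = 0.5
        draws = sample_prior_predictive_priors(
            TraitPriors(mu_sd=0.5), S=1, n=20_000, seed=0
        )
        m = draws["prob_mean_0"]
        assert abs(m.mean() - 0.5) < 0.01
        assert ((m > 0.25) & (m < 0.75)).mean() > 0.8

    def test_correlation_prior_symmetric(self):
        draws = sample_prior_predictive_priors(TraitPriors(), S=2, n=20_000, seed=1)
        rho = draws["rho_01"]
        assert abs(rho.mean()) < 0.02
        assert abs(np.mean(rho > 0) - 0.5) < 0.02


@pytest.fixture(scope="module")
def recovery_fit(htsm_restricted):
    """One moderately large fit reused across recovery assertions."""
    spec = TraitPopulationSpec(
        mu_probit=ndtri(np.array([0.6, 0.5, 0.3, 0.7])),  # D, a, b, d order
        sigma_probit=np.full(4, 0.4),
    )
    data, theta, _ = gen_trait_mpt(
        100, {"E": 100, "U": 100, "N": 100}, spec, htsm_restricted, seed=21
    )
    fit = quiet_fit(
        htsm_restricted, data,
        settings=McmcSettings(n_iter=2500, n_burnin=800, thin=2, n_chains=2,
                              seed=2),
    )
    return fit, spec, theta


class TestFitTrait:
    def test_group_mean_recovery(self, recovery_fit, htsm_restricted):
        fit, spec, _ = recovery_fit
        truth = ndtr(spec.mu_probit)
        for j, p in enumerate(htsm_restricted.parameters):
            est = fit.draws.flat(f"mean_{p}").mean()
            assert est == pytest.approx(truth[j], abs=0.05)

    def test_sigma_recovery(self, recovery_fit, htsm_restricted):
        fit, spec, _ = recovery_fit
        for j, p in enumerate(htsm_restricted.parameters):
            est = fit.draws.flat(f"sigma_{p}").mean()
            assert est == pytest.approx(0.4, abs=0.2)

    def test_individual_theta_shrinks_toward_truth(self, recovery_fit,
                                                   htsm_restricted):
        fit, _, theta = recovery_fit
        est = fit.theta_posterior_mean()
        err = np.abs(est - theta).mean()
        assert err < 0.06

    def test_covariance_reconstruction_positive_definite(self, recovery_fit,
                                                         htsm_restricted):
        fit, _, _ = recovery_fit
        params = htsm_restricted.parameters
        sig = np.stack([fit.draws.flat(f"sigma_{p}") for p in params])
        n = sig.shape[1]
        rng = np.random.default_rng(0)
        for m in rng.choice(n, size=50, replace=False):
            corr = np.eye(4)
            for i, p in enumerate(params):
                for j, q in enumerate(params[i + 1:], start=i + 1):
                    corr[i, j] = corr[j, i] = fit.draws.flat(f"rho_{p}_{q}")[m]
            cov = corr * np.outer(sig[:, m], sig[:, m])
            assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_seed_determinism(self, htsm_restricted, htsm_table):
        data, _ = htsm_table
        s = McmcSettings(n_iter=300, n_burnin=100, thin=2, n_chains=2, seed=5)
        f1 = quiet_fit(htsm_restricted, data, settings=s)
        f2 = quiet_fit(htsm_restricted, data, settings=s)
        assert np.array_equal(f1.draws.draws, f2.draws.draws)

    def test_nonconvergence_warns(self, htsm_restricted, htsm_table):
        data, _ = htsm_table
        s = McmcSettings(n_iter=80, n_burnin=20, thin=1, n_chains=2, seed=5)
        with pytest.warns(UserWarning, match="not have converged"):
            fit_trait(htsm_restricted, data, settings=s)


@pytest.fixture(scope="module")
def slope_fit(htsm_restricted):
    spec = TraitPopulationSpec(
        mu_probit=np.array([0.4, 0.3, -0.1, 0.6]),
        sigma_probit=np.array([0.3, 0.5, 0.4, 0.8]),
        slopes={"D_1": -0.4, "d_1": 0.5},
    )
    data, _, cov = gen_trait_mpt(
        60, {"E": 30, "U": 30, "N": 60}, spec, htsm_restricted, seed=31
    )
    pred = PredictorSpec.parse(["D_1 d_1 ; x"])
    fit = quiet_fit(
        htsm_restricted, data, cov, pred,
        settings=McmcSettings(n_iter=2500, n_burnin=800, thin=2,
                              n_chains=2, seed=3),
    )
    return fit, cov, data


class TestPredictors:
    def test_slope_sign_and_magnitude(self, slope_fit):
        fit, _, _ = slope_fit
        bD = fit.draws.flat("beta_D_1_x")
        bd = fit.draws.flat("beta_d_1_x")
        assert bD.mean() == pytest.approx(-0.4, abs=0.25)
        assert bd.mean() == pytest.approx(0.5, abs=0.35)
        assert np.quantile(bD, 0.975) < 0

    def test_rescaling_invariance(self, htsm_restricted, slope_fit):
        """Multiplying a covariate by a constant leaves the standardized
        slope invariant (same seed) and divides the raw slope."""
        fit, cov, data = slope_fit
        # a power-of-two factor keeps the standardized design bit-identical
        scaled = cov * 4.0
        pred = PredictorSpec.parse(["D_1 d_1 ; x"])
        s = McmcSettings(n_iter=600, n_burnin=200, thin=2, n_chains=2, seed=4)
        f1 = quiet_fit(htsm_restricted, data, cov, pred, settings=s)
        f2 = quiet_fit(htsm_restricted, data, scaled, pred, settings=s)
        assert np.allclose(
            f1.draws.get("beta_D_1_x"), f2.draws.get("beta_D_1_x")
        )
        assert np.allclose(
            f1.draws.get("betaU_D_1_x"), 4.0 * f2.draws.get("betaU_D_1_x")
        )

    def test_empty_spec_reduces_to_plain_model(self, htsm_restricted,
                                               htsm_table):
        """With no predictors the regression model is exactly the basic
        latent-trait model (identical draws under the same seed)."""
        data, _ = htsm_table
        cov = pd.DataFrame({"x": np.zeros(data.n_participants) + 1.5})
        s = McmcSettings(n_iter=300, n_burnin=100, thin=2, n_chains=2, seed=6)
        base = quiet_fit(htsm_restricted, data, settings=s)
        with_cov = quiet_fit(htsm_restricted, data, cov, PredictorSpec(),
                             settings=s)
        assert np.array_equal(base.draws.draws, with_cov.draws.draws)


class TestDiscreteFactors:
    def test_two_group_shift_recovered(self, htsm_restricted):
        """Fixed two-level factor with a true probit shift of 0.5 on D."""
        spec = TraitPopulationSpec(
            mu_probit=np.array([0.3, 0.3, -0.1, 0.6]),
            sigma_probit=np.array([0.3, 0.5, 0.4, 0.6]),
        )
        rng = np.random.default_rng(55)
        halves = []
        for shift in (+0.25, -0.25):
            sp = TraitPopulationSpec(
                spec.mu_probit + np.array([shift, 0, 0, 0]),
                spec.sigma_probit,
            )
            data, _, _ = gen_trait_mpt(
                60, {"E": 50, "U": 50, "N": 100}, sp, htsm_restricted,
                seed=int(rng.integers(2**31)),
            )
            halves.append(data.counts)
        counts = np.concatenate(halves, axis=0)
        data = FrequencyTable(
            counts, list(htsm_restricted.category_labels),
            dict(htsm_restricted.categories),
        )
        cov = pd.DataFrame({"grp": ["g1"] * 60 + ["g2"] * 60})
        pred = PredictorSpec.parse(["D_1 ; grp"], {"grp": "fixed_factor"})
        fit = quiet_fit(
            htsm_restricted, data, cov, pred,
            settings=McmcSettings(n_iter=2000, n_burnin=700, thin=2,
                                  n_chains=2, seed=7),
        )
        means = hmpt.group_means_by_factor(fit, "grp")
        d1 = means.loc[("D_1", "g1"), "mean"]
        d2 = means.loc[("D_1", "g2"), "mean"]
        true_diff = ndtr(0.55) - ndtr(0.05)
        assert (d1 - d2) == pytest.approx(true_diff, abs=0.15)
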