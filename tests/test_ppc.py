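import warnings

import numpy as np
import pytest

from hmpt.datagen import gen_beta_mpt, gen_trait_mpt, TraitPopulationSpec
from hmpt.likelihood import FrequencyTable, compile_model, expected_frequencies
from hmpt.mcmc import McmcSettings
from hmpt.ppc import (
    T1_statistic,
    T2_statistic,
    dic,
    expected_moments,
    posterior_predictive_samples,
    ppp,
)
from hmpt.trait import fit_trait
from hmpt.beta import fit_beta


def small_fit(model, data, seed=1, n_iter=1200, n_burnin=400):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_beta(
            model, data,
            settings=McmcSettings(n_iter=n_iter, n_burnin=n_burnin, thin=2,
                                  n_chains=2, seed=seed),
        )


class TestT1:
    def test_zero_when_observed_equals_expected(self):
        counts = np.array([[6.0, 4.0], [4.0, 6.0]])
        assert T1_statistic(counts, counts.mean(axis=0)) == 0.0

    def test_hand_value(self):
        counts = np.array([[6.0, 4.0]])
        assert T1_statistic(counts, np.array([5.0, 5.0])) == pytest.approx(0.4)

    def test_invariant_to_duplicating_participants(self):
        counts = np.array([[6.0, 4.0], [2.0, 8.0]])
        e = np.array([5.0, 5.0])
        doubled = np.vstack([counts, counts])
        assert T1_statistic(counts, e) == pytest.approx(T1_statistic(doubled, e))


class TestT2:
    def test_zero_at_empirical_covariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(6, 3)).astype(float)
        cov = np.cov(counts.T, ddof=1)
        sd = np.sqrt(np.maximum(np.diag(cov), 1e-6))
        assert T2_statistic(counts, cov, sd) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        counts = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        # off-diagonal sample covariance (ddof=1): -1
        expected_cov = np.zeros((2, 2))
        sd = np.array([2.0, 0.5])
        want = abs(-1.0 - 0.0) / (2.0 * 0.5)
        assert T2_statistic(counts, expected_cov, sd) == pytest.approx(want)

    def test_invariant_to_category_order(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(5, 3)).astype(float)
        cov = np.eye(3) * 2.0
        sd = np.sqrt(np.diag(cov))
        perm = [2, 0, 1]
        a = T2_statistic(counts, cov, sd)
        b = T2_statistic(counts[:, perm], cov[np.ix_(perm, perm)], sd[perm])
        assert a == pytest.approx(b)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="2 participants"):
            T2_statistic(np.array([[1.0, 2.0]]), np.eye(2), np.ones(2))


class TestExpectedMoments:
    def test_lln_match_with_simulated_tables(self, two_tree_model):
        """Mean of simulated frequencies converges to the analytic
        expectation when theta is held fixed."""
        from hmpt.datagen import gen_mpt

        theta = np.array([[0.7, 0.3], [0.4, 0.6]])
        items = {"old": 100_000, "new": 100_000}
        table = gen_mpt(theta, two_tree_model, items, seed=5)
        e = expected_frequencies(theta, items, two_tree_model)
        assert np.max(np.abs(table.counts - e) / items["old"]) < 0.01

    def test_covariance_formula_against_simulation(self, toy_model):
        """Analytic multinomial covariance matches brute-force simulation."""
        rng = np.random.default_rng(3)
        theta = np.array([[0.6, 0.4], [0.2, 0.7], [0.8, 0.1]])
        compiled = compile_model(toy_model)
        data = FrequencyTable(
            np.full((3, 2), 10), list(toy_model.category_labels),
            dict(toy_model.categories),
        )
        mean_exp, cov_exp, sd_exp = expected_moments(theta, data, compiled)
        sims = []
        from hmpt.likelihood import category_probabilities

        probs = category_probabilities(theta, compiled)
        for _ in range(4000):
            t = np.stack([rng.multinomial(20, probs[p]) for p in range(3)])
            sims.append(t)
        sims = np.array(sims, dtype=float)
        mean_sim = sims.mean(axis=(0, 1))
        cov_sim = np.mean(
            [np.cov(s.T, ddof=1) for s in sims], axis=0
        )
        assert np.allclose(mean_exp, mean_sim, atol=0.15)
        assert np.allclose(cov_exp, cov_sim, atol=0.4)


@pytest.fixture(scope="module")
def fitted_beta(htsm_restricted):
    mean = np.array([0.6, 0.55, 0.5, 0.65])
    sd = np.array([0.1, 0.12, 0.1, 0.12])
    data, _ = gen_beta_mpt(
        30, {"E": 40, "U": 40, "N": 40}, mean, sd, htsm_restricted, seed=17
    )
    return small_fit(htsm_restricted, data, seed=2, n_iter=2000, n_burnin=600)


class TestPosteriorPredictive:
    def test_totals_preserved(self, fitted_beta):
        tables = posterior_predictive_samples(fitted_beta, M=5, seed=0)
        obs_tot = fitted_beta.data.tree_totals()
        compiled = compile_model(fitted_beta.model)
        for t in tables:
            sim = FrequencyTable(
                t, list(fitted_beta.model.category_labels),
                dict(fitted_beta.model.categories),
            )
            assert np.array_equal(sim.tree_totals(), obs_tot)

    def test_reproducible_with_seed(self, fitted_beta):
        a = posterior_predictive_samples(fitted_beta, M=3, seed=9)
        b = posterior_predictive_samples(fitted_beta, M=3, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_group_level_varies_participants(self, fitted_beta):
        tables = posterior_predictive_samples(
            fitted_beta, M=3, level="group", seed=4
        )
        assert len(tables) == 3


class TestPpp:
    def test_well_specified_fit_not_extreme(self, fitted_beta):
        res = ppp(fitted_beta, M=150, seed=3)
        assert 0.0 <= res.ppp_T1 <= 1.0
        assert 0.0 <= res.ppp_T2 <= 1.0
        assert 0.05 < res.ppp_T1 < 0.95
        assert res.individual_ppp.shape == (30,)
        assert np.all((res.individual_ppp >= 0) & (res.individual_ppp <= 1))

    def test_misspecified_data_detected(self, htsm_restricted):
        """Swapping category columns produces data no 2HTSM can fit."""
        mean = np.array([0.7, 0.55, 0.5, 0.7])
        sd = np.array([0.1, 0.1, 0.1, 0.1])
        data, _ = gen_beta_mpt(
            30, {"E": 40, "U": 40, "N": 40}, mean, sd, htsm_restricted, seed=19
        )
        counts = data.counts.copy()
        # swap E_A <-> E_N for half the sample: grossly non-multinomial rows
        k1 = data.category_labels.index("E_A")
        k2 = data.category_labels.index("E_N")
        counts[::2, [k1, k2]] = counts[::2, [k2, k1]]
        broken = FrequencyTable(counts, list(data.category_labels),
                                dict(data.tree_of_category))
        fit = small_fit(htsm_restricted, broken, seed=4, n_iter=2000,
                        n_burnin=600)
        res = ppp(fit, M=150, seed=5)
        assert res.ppp_T2 < 0.05 or res.ppp_T1 < 0.05


class TestDic:
    def test_degenerate_posterior_zero_pd(self, fitted_beta):
        fit = fitted_beta
        import copy

        frozen = copy.deepcopy(fit)
        theta_cols = [i for i, n in enumerate(frozen.draws.names)
                      if n.startswith("theta_")]
        for c in theta_cols:
            frozen.draws.draws[:, :, c] = frozen.draws.draws[0, 0, c]
        d, p_d, dbar = dic(frozen)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(dbar)

    def test_pd_positive_on_real_fit(self, fitted_beta):
        d, p_d, dbar = dic(fitted_beta)
        assert p_d > 0
        assert d == pytest.approx(dbar + p_d)

    def test_smaller_true_model_preferred(self, two_tree_model):
        """Data generated from the nested model with guessing fixed at .5:
        its DIC beats the 2-parameter model's in most replications."""
        import hmpt

        small = hmpt.apply_restrictions(
            two_tree_model,
            hmpt.parse_restrictions(["g = 0.5"], two_tree_model),
        )
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            spec = TraitPopulationSpec(np.array([0.4]), np.array([0.4]))
            data, _, _ = gen_trait_mpt(
                30, {"old": 40, "new": 40}, spec, small, seed=200 + rep
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = McmcSettings(n_iter=1500, n_burnin=500, thin=2,
                                 n_chains=2, seed=rep)
                fit_small = fit_trait(small, data, settings=s)
                fit_big = fit_trait(
                    two_tree_model, data.aligned_to(two_tree_model), settings=s
                )
            wins += dic(fit_small)[0] <= dic(fit_big)[0]
        assert wins >= 4
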