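import numpy as np
import pytest
from scipy import stats

from hmpt.mcmc import (
    McmcSettings,
    adapt_step_size,
    extend_run,
    gelman_rubin,
    run_chains,
    summarize_draws,
)


class BetaBinomialKernel:
    """Conjugate Gibbs toy: rate ~ Beta(a, b), x successes in n trials.

    The exact posterior Beta(a + x, b + n - x) provides an independent
    oracle for the engine.
    """

    param_names = ["rate"]

    def __init__(self, a=2.0, b=3.0, x=7, n=20):
        self.a, self.b, self.x, self.n = a, b, x, n

    def init(self, rng):
        return {"rate": rng.uniform()}

    def sweep(self, state, rng, iteration, adapting):
        state["rate"] = rng.beta(self.a + self.x, self.b + self.n - self.x)

    def record(self, state):
        return np.array([state["rate"]])


class GaussianRWKernel:
    """Adaptive random-walk Metropolis on a known 2-D Gaussian target."""

    param_names = ["x0", "x1"]

    def __init__(self, cov):
        self.cov = np.asarray(cov)
        self.prec = np.linalg.inv(self.cov)

    def init(self, rng):
        return {"x": rng.standard_normal(2), "ls": np.zeros(2)}

    def log_posterior(self, state):
        x = state["x"]
        return -0.5 * x @ self.prec @ x

    def sweep(self, state, rng, iteration, adapting):
        step = adapt_step_size(iteration) if adapting else 0.0
        for j in range(2):
            prop = state["x"].copy()
            prop[j] += np.exp(state["ls"][j]) * rng.standard_normal()
            delta = -0.5 * prop @ self.prec @ prop + 0.5 * state["x"] @ self.prec @ state["x"]
            accepted = np.log(rng.random()) < delta
            if accepted:
                state["x"] = prop
            if adapting:
                state["ls"][j] += step * (float(accepted) - 0.35)

    def record(self, state):
        return state["x"].copy()


class TestRunChains:
    def test_conjugate_posterior_mean(self):
        kernel = BetaBinomialKernel()
        settings = McmcSettings(n_iter=3000, n_burnin=500, thin=1,
                                n_chains=2, seed=3)
        draws = run_chains(kernel, settings)
        x = draws.flat("rate")
        exact_mean = (2 + 7) / (2 + 3 + 20)
        exact_sd = np.sqrt(stats.beta.var(9, 16))
        mc_se = exact_sd / np.sqrt(len(x))  # i.i.d. draws
        assert abs(x.mean() - exact_mean) < 3 * mc_se

    def test_same_seed_bit_identical(self):
        kernel = GaussianRWKernel(np.eye(2))
        settings = McmcSettings(n_iter=500, n_burnin=100, thin=2,
                                n_chains=2, seed=9)
        d1 = run_chains(kernel, settings)
        d2 = run_chains(kernel, settings)
        assert np.array_equal(d1.draws, d2.draws)

    def test_target_covariance_recovered(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        kernel = GaussianRWKernel(cov)
        settings = McmcSettings(n_iter=30_000, n_burnin=3_000, thin=3,
                                n_chains=2, seed=1)
        draws = run_chains(kernel, settings)
        sample = np.column_stack([draws.flat("x0"), draws.flat("x1")])
        est = np.cov(sample.T)
        assert np.all(np.abs(est - cov) / np.abs(cov).max() < 0.10)
        conv = gelman_rubin(draws)
        assert conv.table["ess"].min() > 1000

    def test_adaptation_frozen_after_burnin(self):
        kernel = GaussianRWKernel(np.eye(2))
        settings = McmcSettings(n_iter=400, n_burnin=200, thin=1,
                                n_chains=1, seed=4)
        draws = run_chains(kernel, settings)
        frozen = draws.final_states[0]["ls"].copy()
        extended = extend_run(draws, kernel, 200)
        assert np.array_equal(extended.final_states[0]["ls"], frozen)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 1000, 1))
        report = gelman_rubin(arr)
        assert report.table["rhat"].iloc[0] < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 500, 1))
        arr[1] += 10.0
        report = gelman_rubin(arr)
        assert report.table["rhat"].iloc[0] > 1.1

    def test_constant_chain_degenerate(self):
        arr = np.ones((2, 100, 1))
        report = gelman_rubin(arr)
        assert bool(report.table["degenerate"].iloc[0])
        assert report.table["rhat"].iloc[0] == 1.0

    def test_agrees_with_arviz(self):
        """Independent cross-check of R-hat/ESS against arviz."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        # mildly autocorrelated chains
        arr = np.empty((3, 800))
        for c in range(3):
            e = rng.standard_normal(800)
            for t in range(1, 800):
                e[t] += 0.5 * e[t - 1]
            arr[c] = e
        ours = gelman_rubin(arr[:, :, None]).table
        theirs_rhat = float(az.rhat(arr.reshape(3, 800)))
        # rank-normalization differs slightly; agreement to a few percent
        assert ours["rhat"].iloc[0] == pytest.approx(theirs_rhat, abs=0.03)
        theirs_ess = float(az.ess(arr.reshape(3, 800)))
        assert ours["ess"].iloc[0] == pytest.approx(theirs_ess, rel=0.25)


class TestExtendRun:
    def test_extend_by_zero_is_identity(self):
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(200, 50, 1, 2, seed=0))
        assert extend_run(draws, kernel, 0) is draws

    def test_retained_length_grows(self):
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(200, 50, 5, 2, seed=0))
        longer = extend_run(draws, kernel, 100)
        assert longer.n_retained == draws.n_retained + 20

    def test_distributionally_equivalent_to_single_run(self):
        """10k-then-extend-10k matches a single 20k run (KS test on the
        conjugate toy, where draws are i.i.d. from the exact posterior)."""
        kernel = BetaBinomialKernel()
        passes = 0
        for rep in range(20):
            short = run_chains(
                kernel, McmcSettings(600, 100, 1, 1, seed=rep)
            )
            both = extend_run(short, kernel, 500)
            single = run_chains(
                kernel, McmcSettings(1100, 100, 1, 1, seed=1000 + rep)
            )
            p = stats.ks_2samp(both.flat("rate"), single.flat("rate")).pvalue
            passes += p > 0.01
        assert passes >= 18

    def test_thin_mismatch_not_possible_via_api(self):
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(200, 50, 5, 2, seed=0))
        # thinning is inherited from the stored settings by construction
        longer = extend_run(draws, kernel, 50)
        assert longer.settings.thin == 5


class TestSummaries:
    def test_constant_draws_zero_sd(self):
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(300, 100, 1, 2, seed=0))
        draws.draws[:, :, 0] = 0.7
        summary = summarize_draws(draws)
        assert summary.loc["rate", "sd"] == 0.0

    def test_standard_normal_quantile(self):
        rng = np.random.default_rng(5)
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(300, 100, 1, 2, seed=0))
        draws.draws[:, :, 0] = rng.standard_normal(draws.draws.shape[:2])
        summary = summarize_draws(draws)
        n = draws.draws[:, :, 0].size
        # MC error of the 2.5% quantile estimator
        se = np.sqrt(0.025 * 0.975 / n) / stats.norm.pdf(-1.96)
        assert summary.loc["rate", "q2.5%"] == pytest.approx(-1.96, abs=4 * se)
        assert summary.loc["rate", "mean"] == pytest.approx(
            summary.loc["rate", "q50%"], abs=0.05
        )

    def test_export_roundtrip(self, tmp_path):
        kernel = BetaBinomialKernel()
        draws = run_chains(kernel, McmcSettings(200, 50, 2, 2, seed=0))
        csv = tmp_path / "draws.csv"
        meta = tmp_path / "draws.json"
        draws.export(csv, meta)
        import json

        import pandas as pd

        df = pd.read_csv(csv)
        assert list(df.columns) == ["chain", "iteration", "rate"]
        assert len(df) == draws.n_chains * draws.n_retained
        info = json.loads(meta.read_text())
        assert info["settings"]["thin"] == 2


def test_prior_recovery_flat_likelihood():
    """A kernel whose likelihood is constant must reproduce its prior."""

    class PriorOnly:
        param_names = ["x"]

        def init(self, rng):
            return {"x": rng.normal(1.0, 2.0)}

        def sweep(self, state, rng, iteration, adapting):
            state["x"] = rng.normal(1.0, 2.0)

        def record(self, state):
            return np.array([state["x"]])

    draws = run_chains(PriorOnly(), McmcSettings(4000, 500, 1, 2, seed=8))
    x = draws.flat("x")
    se = 2.0 / np.sqrt(len(x))
    assert abs(x.mean() - 1.0) < 3 * se
    assert abs(x.std() - 2.0) < 3 * se
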