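"""Beta-MPT model.

Each MPT parameter s has an independent beta population distribution:
theta_ps ~ Beta(alpha_s, beta_s), with Gamma(shape 1, rate 0.1) hyperpriors
on both shape parameters. Group-level location and spread are reported via
the beta moments E = alpha/(alpha+beta) and
Var = alpha*beta / ((alpha+beta+1)(alpha+beta)^2).

Sampling is componentwise random-walk Metropolis: the individual
parameters on the logit scale (unconstrained proposals, with the Jacobian
theta(1-theta) folded into the target) and the shape parameters on the log
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .eqn import MptModel
from .likelihood import CompiledModel, FrequencyTable, compile_model, THETA_EPS
from .mcmc import (
    ConvergenceReport,
    McmcSettings,
    PosteriorDraws,
    adapt_step_size,
    run_chains,
    summarize_draws,
)
from .trait import _check_convergence, pooled_ml_theta

__all__ = [
    "BetaPriors",
    "BetaFit",
    "beta_moments",
    "moments_to_shapes",
    "fit_beta",
]


@dataclass(frozen=True)
class BetaPriors:
    """Gamma hyperpriors on the beta shape parameters (shape 1, rate 0.1)."""

    alpha_shape: float = 1.0
    alpha_rate: float = 0.1
    beta_shape: float = 1.0
    beta_rate: float = 0.1

    def __post_init__(self) -> None:
        for v in (self.alpha_shape, self.alpha_rate, self.beta_shape, self.beta_rate):
            if v <= 0:
                raise ValueError("gamma hyperprior parameters must be positive")


def beta_moments(alpha, beta):
    """Mean and variance of Beta(alpha, beta)."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("shape parameters must be positive")
    s = alpha + beta
    mean = alpha / s
    var = alpha * beta / ((s + 1.0) * s**2)
    return mean, var


def moments_to_shapes(mean, sd):
    """Invert the beta moments: (mean, sd) -> (alpha, beta).

    Requires sd^2 < mean*(1-mean); a beta distribution cannot be more
    dispersed than the matching Bernoulli.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    var = sd**2
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise ValueError("mean must lie strictly inside (0, 1)")
    if np.any(var >= mean * (1 - mean)):
        raise ValueError(
            "sd^2 must be smaller than mean*(1-mean); no beta distribution "
            "has these moments"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


class _BetaKernel:
    """Componentwise Metropolis kernel for the beta-MPT model."""

    def __init__(
        self,
        compiled: CompiledModel,
        data: FrequencyTable,
        priors: BetaPriors,
        target_acceptance: float = 0.35,
    ) -> None:
        self.compiled = compiled
        model = compiled.model
        self.S = model.n_parameters
        self.P = data.n_participants
        self.counts = data.counts.astype(float)
        self.priors = priors
        self.target = target_acceptance
        self.theta_start = pooled_ml_theta(data, compiled)
        names = []
        for p in model.parameters:
            names.append(f"mean_{p}")
        for p in model.parameters:
            names.append(f"sd_{p}")
        for p in model.parameters:
            names.append(f"alpha_{p}")
        for p in model.parameters:
            names.append(f"beta_{p}")
        for p in model.parameters:
            for rid in data.row_ids:
                names.append(f"theta_{p}[{rid}]")
        self.param_names = names

    def _loglik_rows(self, theta: np.ndarray) -> np.ndarray:
        c = self.compiled
        th = np.clip(theta, THETA_EPS, 1 - THETA_EPS)
        logb = np.log(th) @ c.expo_a.T + np.log1p(-th) @ c.expo_b.T + np.log(c.const)
        probs = np.exp(logb) @ c.branch_to_cat
        return np.sum(self.counts * np.log(np.maximum(probs, 1e-300)), axis=1)

    def init(self, rng: np.random.Generator) -> dict:
        x0 = logit(self.theta_start)
        X = x0[None, :] + rng.normal(0.0, 0.4, size=(self.P, self.S))
        theta = expit(X)
        state = {
            "theta": theta,
            "alpha": np.exp(rng.normal(np.log(2.0), 0.3, size=self.S)),
            "beta": np.exp(rng.normal(np.log(2.0), 0.3, size=self.S)),
            "ls_theta": np.full((self.P, self.S), np.log(0.8)),
            "ls_shape": np.full((2, self.S), np.log(0.4)),
            "ll": None,
        }
        state["ll"] = self._loglik_rows(theta)
        return state

    def log_posterior(self, state: dict) -> float:
        return float(np.sum(state["ll"]))

    @staticmethod
    def _shape_logtarget(a: float, b: float, sum_log: float, sum_log1m: float,
                         P: int, shape: float, rate: float,
                         which: str) -> float:
        # beta-density part in (a, b) across P participants
        val = P * (gammaln(a + b) - gammaln(a) - gammaln(b))
        val += (a - 1.0) * sum_log + (b - 1.0) * sum_log1m
        # Gamma prior + log Jacobian of the log-scale proposal
        x = a if which == "a" else b
        val += (shape - 1.0) * np.log(x) - rate * x + np.log(x)
        return val

    def sweep(self, state: dict, rng: np.random.Generator, iteration: int,
              adapting: bool) -> None:
        S, P = self.S, self.P
        step = adapt_step_size(iteration) if adapting else 0.0
        theta = state["theta"]
        ll = state["ll"]
        alpha, beta = state["alpha"], state["beta"]

        # individual parameters, logit-scale random walk, vectorized over p
        for s in range(S):
            x = logit(np.clip(theta[:, s], THETA_EPS, 1 - THETA_EPS))
            prop_x = x + np.exp(state["ls_theta"][:, s]) * rng.standard_normal(P)
            prop_t = expit(prop_x)
            theta_prop = theta.copy()
            theta_prop[:, s] = prop_t
            ll_prop = self._loglik_rows(theta_prop)
            # Beta(alpha, beta) prior with logit Jacobian: exponents alpha, beta
            lp_cur = alpha[s] * np.log(theta[:, s]) + beta[s] * np.log1p(-theta[:, s])
            lp_prop = alpha[s] * np.log(prop_t) + beta[s] * np.log1p(-prop_t)
            accept = np.log(rng.random(P)) < (ll_prop - ll + lp_prop - lp_cur)
            theta[accept, s] = prop_t[accept]
            ll = np.where(accept, ll_prop, ll)
            if adapting:
                state["ls_theta"][:, s] += step * (accept.astype(float) - self.target)
        state["ll"] = ll

        # shape parameters, log-scale random walk
        pri = self.priors
        for s in range(S):
            sum_log = float(np.sum(np.log(theta[:, s])))
            sum_log1m = float(np.sum(np.log1p(-theta[:, s])))
            for wi, which in enumerate(("a", "b")):
                a, b = alpha[s], beta[s]
                cur_x = a if which == "a" else b
                prop = cur_x * np.exp(
                    np.exp(state["ls_shape"][wi, s]) * rng.standard_normal()
                )
                pa, pb = (prop, b) if which == "a" else (a, prop)
                shape, rate = (
                    (pri.alpha_shape, pri.alpha_rate)
                    if which == "a"
                    else (pri.beta_shape, pri.beta_rate)
                )
                num = self._shape_logtarget(pa, pb, sum_log, sum_log1m, P,
                                            shape, rate, which)
                den = self._shape_logtarget(a, b, sum_log, sum_log1m, P,
                                            shape, rate, which)
                accepted = np.log(rng.random()) < num - den
                if accepted:
                    if which == "a":
                        alpha[s] = prop
                    else:
                        beta[s] = prop
                if adapting:
                    state["ls_shape"][wi, s] += step * (float(accepted) - self.target)

    def record(self, state: dict) -> np.ndarray:
        mean, var = beta_moments(state["alpha"], state["beta"])
        return np.concatenate(
            [
                mean,
                np.sqrt(var),
                state["alpha"],
                state["beta"],
                state["theta"].T.reshape(-1),
            ]
        )


@dataclass
class BetaFit:
    """Fitted beta-MPT model."""

    model: MptModel
    data: FrequencyTable
    draws: PosteriorDraws
    priors: BetaPriors
    convergence: ConvergenceReport

    kind: str = "beta"

    @property
    def parameters(self) -> tuple[str, ...]:
        return self.model.parameters

    def summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        sel = [n for n in self.draws.names if not n.startswith("theta_")]
        return summarize_draws(self.draws, probs, names=sel)

    def theta_draws(self, parameter: str) -> np.ndarray:
        names = self.draws.matching(f"theta_{parameter}[")
        return np.stack([self.draws.flat(n) for n in names])

    def theta_posterior_mean(self) -> np.ndarray:
        out = np.empty((self.data.n_participants, len(self.parameters)))
        for j, p in enumerate(self.parameters):
            out[:, j] = self.theta_draws(p).mean(axis=1)
        return out


def fit_beta(
    model: MptModel,
    data: FrequencyTable,
    priors: BetaPriors | None = None,
    settings: McmcSettings | None = None,
) -> BetaFit:
    """Fit the beta-MPT model by MCMC (interface mirrors :func:`fit_trait`)."""
    priors = priors or BetaPriors()
    settings = settings or McmcSettings()
    data = data.aligned_to(model)
    compiled = compile_model(model)
    kernel = _BetaKernel(compiled, data, priors, settings.target_acceptance)
    draws = run_chains(kernel, settings)
    conv = _check_convergence(draws)
    return BetaFit(model, data, draws, priors, conv)
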