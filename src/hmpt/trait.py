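"""Latent-trait MPT model.

Individual parameter vectors are modeled on the probit scale as

    Phi^{-1}(theta_p) = mu + X_p beta + delta_p,      delta_p ~ MVN(0, Sigma)

with a scaled inverse-Wishart prior on the covariance matrix,
Sigma = diag(xi) Q diag(xi), Q ~ InvWishart(V = I, df = S + 1),
xi_s ~ Uniform[0, 10], and standard-normal priors on the group means mu_s
(these imply uniform distributions for the group means Phi(mu_s) on the
probability scale). Continuous predictors enter as z-standardized columns
of X with slopes beta_sk ~ Normal(0, g_s) and g_s ~ InverseGamma(1/2,
v^2/2) (v = 1: a multivariate Cauchy prior on the slopes of a parameter).
Discrete between-subjects factors enter the same linear term, sum-to-zero
coded as fixed effects or indicator-coded as exchangeable random effects
with an inverse-chi^2(1) variance.

Sampling is Metropolis-within-Gibbs: componentwise adaptive random-walk
Metropolis for the probit values z_ps (the multinomial likelihood is not
conjugate), conjugate Gibbs blocks for mu, the slopes, Q and the slope
variances, and bounded random-walk Metropolis for the scaling factors xi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri  # Phi and probit

from .eqn import MptModel
from .likelihood import (
    CompiledModel,
    FrequencyTable,
    compile_model,
    THETA_EPS,
)
from .mcmc import (
    ConvergenceReport,
    McmcSettings,
    PosteriorDraws,
    adapt_step_size,
    gelman_rubin,
    run_chains,
    summarize_draws,
)

__all__ = [
    "TraitPriors",
    "PredictorSpec",
    "DesignBlock",
    "TraitFit",
    "build_design",
    "fit_trait",
    "sample_prior_predictive_priors",
    "pooled_ml_theta",
]

_Z_BOUND = 40.0  # keeps probit values finite; theta is clipped in the likelihood


@dataclass(frozen=True)
class TraitPriors:
    """Hyperpriors of the latent-trait model (see module docstring).

    Normal priors are parameterized by (mean, sd) — note that BUGS-style
    notation uses precision, so e.g. ``dnorm(0, 4)`` corresponds to
    ``mu_sd = 0.5``.
    """

    mu_mean: float | np.ndarray = 0.0
    mu_sd: float | np.ndarray = 1.0
    V: np.ndarray | None = None  # default identity
    df: int | None = None        # default S + 1
    xi_low: float = 0.0
    xi_high: float = 10.0
    v_slope: float = 1.0         # scale v of the inverse-chi^2 slope prior
    fix_g: bool = False          # g_s = 1 instead of the inverse-chi^2 prior

    def resolved(self, S: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        mu0 = np.broadcast_to(np.asarray(self.mu_mean, float), (S,)).copy()
        sd0 = np.broadcast_to(np.asarray(self.mu_sd, float), (S,)).copy()
        V = np.eye(S) if self.V is None else np.asarray(self.V, float)
        df = S + 1 if self.df is None else int(self.df)
        if V.shape != (S, S) or not np.allclose(V, V.T):
            raise ValueError("V must be a symmetric S x S matrix")
        if df < S:
            raise ValueError("Wishart df must be >= S")
        if not (0.0 <= self.xi_low < self.xi_high):
            raise ValueError("xi bounds must satisfy 0 <= low < high")
        return mu0, sd0, V, df


@dataclass(frozen=True)
class PredictorSpec:
    """Which covariates predict which MPT parameters.

    ``assignments`` pairs a set of parameter names with a set of covariate
    names (e.g. ``[(["a"], ["pc"]), (["D", "d"], ["age"])]``); ``pred_type``
    maps each covariate to ``continuous`` (default), ``fixed_factor``, or
    ``random_factor``.
    """

    assignments: tuple = ()
    pred_type: dict[str, str] = field(default_factory=dict)
    v_scale: float = 1.0

    @staticmethod
    def parse(entries: list[str], pred_type: dict[str, str] | None = None
              ) -> "PredictorSpec":
        """Parse ``"a D ; pc age"``-style assignment strings."""
        assignments = []
        for entry in entries:
            left, _, right = entry.partition(";")
            params = left.replace(",", " ").split()
            covs = right.replace(",", " ").split()
            if not params or not covs:
                raise ValueError(f"malformed predictor assignment {entry!r}")
            assignments.append((tuple(params), tuple(covs)))
        return PredictorSpec(tuple(assignments), dict(pred_type or {}))

    def covariates_for(self, parameter: str) -> list[str]:
        out: list[str] = []
        for params, covs in self.assignments:
            if parameter in params:
                for c in covs:
                    if c not in out:
                        out.append(c)
        return out

    def type_of(self, covariate: str) -> str:
        t = self.pred_type.get(covariate, "continuous")
        if t not in ("continuous", "fixed_factor", "random_factor"):
            raise ValueError(f"unknown predictor type {t!r} for {covariate!r}")
        return t


@dataclass
class DesignBlock:
    """One predictor group inside a parameter's design matrix."""

    covariate: str
    kind: str                    # continuous | fixed_factor | random_factor
    columns: list[str]           # column labels
    sl: slice                    # column slice within X_s
    sd: float | None = None      # population SD (continuous, for beta_unstd)
    levels: list[str] | None = None


@dataclass
class ParameterDesign:
    """Design matrix and block structure for one MPT parameter."""

    X: np.ndarray                # (P, K_s); K_s may be 0
    blocks: list[DesignBlock]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_design(
    covariates: pd.DataFrame | None,
    spec: PredictorSpec,
    parameters: tuple[str, ...],
) -> dict[str, ParameterDesign]:
    """Per-parameter design matrices.

    Continuous columns are z-standardized (mean 0, variance 1, population
    divisor). Fixed factors are sum-to-zero coded with L-1 columns; random
    factors are indicator-coded with L columns sharing one variance.
    """
    designs: dict[str, ParameterDesign] = {}
    P = 0 if covariates is None else len(covariates)
    for s in parameters:
        covs = spec.covariates_for(s)
        if covs and covariates is None:
            raise ValueError("predictors requested but no covariate table given")
        mats: list[np.ndarray] = []
        blocks: list[DesignBlock] = []
        start = 0
        for cov in covs:
            if cov not in covariates.columns:
                raise KeyError(f"covariate {cov!r} not in covariate table")
            col = covariates[cov]
            kind = spec.type_of(cov)
            if kind == "continuous":
                x = col.to_numpy(dtype=float)
                sd = float(x.std())  # population divisor
                if sd == 0:
                    raise ValueError(f"covariate {cov!r} has zero variance")
                mats.append(((x - x.mean()) / sd)[:, None])
                blocks.append(
                    DesignBlock(cov, kind, [cov], slice(start, start + 1), sd=sd)
                )
                start += 1
            else:
                levels = list(pd.unique(col.astype(str)))
                counts = col.astype(str).value_counts()
                if len(levels) < 2:
                    raise ValueError(f"factor {cov!r} needs >= 2 levels")
                if (counts == 0).any():
                    raise ValueError(f"factor {cov!r} has an empty level")
                codes = col.astype(str).to_numpy()
                if kind == "fixed_factor":
                    # sum-to-zero contrasts: L-1 columns, last level = -1
                    L = len(levels)
                    X = np.zeros((P, L - 1))
                    for j, lev in enumerate(levels[:-1]):
                        X[codes == lev, j] = 1.0
                        X[codes == levels[-1], j] = -1.0
                    cols = [f"{cov}[{lev}]" for lev in levels[:-1]]
                else:
                    L = len(levels)
                    X = np.zeros((P, L))
                    for j, lev in enumerate(levels):
                        X[codes == lev, j] = 1.0
                    cols = [f"{cov}[{lev}]" for lev in levels]
                mats.append(X)
                blocks.append(
                    DesignBlock(cov, kind, cols, slice(start, start + X.shape[1]),
                                levels=levels)
                )
                start += X.shape[1]
        X = np.concatenate(mats, axis=1) if mats else np.zeros((P, 0))
        designs[s] = ParameterDesign(X, blocks)
    return designs


def pooled_ml_theta(data: FrequencyTable, compiled: CompiledModel) -> np.ndarray:
    """Maximum-likelihood parameter vector for the pooled (summed) counts.

    Used as a cheap data-informed starting point for the samplers; for an
    all-zero table the likelihood is flat and 0.5 is returned everywhere.
    """
    pooled = data.counts.sum(axis=0, keepdims=True).astype(float)
    if pooled.sum() == 0:
        return np.full(compiled.model.n_parameters, 0.5)

    from .likelihood import log_likelihood

    table = FrequencyTable(
        pooled, list(data.category_labels), dict(data.tree_of_category), ["pooled"]
    )

    def negll(x: np.ndarray) -> float:
        theta = 1.0 / (1.0 + np.exp(-x))
        return -log_likelihood(theta[None, :], table, compiled)

    S = compiled.model.n_parameters
    best = None
    for start in (np.zeros(S), np.full(S, 0.5), np.full(S, -0.5)):
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"maxiter": 400 * S, "xatol": 1e-4,
                                         "fatol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    theta = 1.0 / (1.0 + np.exp(-best.x))
    return np.clip(theta, 0.02, 0.98)


class _TraitKernel:
    """Metropolis-within-Gibbs kernel for the latent-trait model."""

    def __init__(
        self,
        compiled: CompiledModel,
        data: FrequencyTable,
        designs: dict[str, ParameterDesign],
        priors: TraitPriors,
        target_acceptance: float = 0.35,
    ) -> None:
        self.compiled = compiled
        model = compiled.model
        self.S = model.n_parameters
        self.P = data.n_participants
        self.counts = data.counts.astype(float)
        self.priors = priors
        self.target = target_acceptance
        self.mu0, self.sd0, self.V, self.df = priors.resolved(self.S)
        self.T0 = np.diag(1.0 / self.sd0**2)
        self.designs = [designs[p] for p in model.parameters]
        self.param_names_model = model.parameters
        self.theta_start = pooled_ml_theta(data, compiled)

        # name registry
        names: list[str] = []
        for p in model.parameters:
            names.append(f"mean_{p}")
        for p in model.parameters:
            names.append(f"mu_{p}")
        for p in model.parameters:
            names.append(f"sigma_{p}")
        for p in model.parameters:
            names.append(f"xi_{p}")
        for i, p in enumerate(model.parameters):
            for q in model.parameters[i + 1:]:
                names.append(f"rho_{p}_{q}")
        for si, p in enumerate(model.parameters):
            d = self.designs[si]
            for blk in d.blocks:
                for col in blk.columns:
                    names.append(f"beta_{p}_{col}")
                if blk.kind == "continuous":
                    names.append(f"betaU_{p}_{blk.covariate}")
        for p in model.parameters:
            for rid in data.row_ids:
                names.append(f"theta_{p}[{rid}]")
        self.param_names = names

    # -- helpers ------------------------------------------------------------

    def _loglik_rows(self, theta: np.ndarray) -> np.ndarray:
        c = self.compiled
        th = np.clip(theta, THETA_EPS, 1 - THETA_EPS)
        logb = (
            np.log(th) @ c.expo_a.T + np.log1p(-th) @ c.expo_b.T + np.log(c.const)
        )
        probs = np.exp(logb) @ c.branch_to_cat
        return np.sum(self.counts * np.log(np.maximum(probs, 1e-300)), axis=1)

    def _mean_matrix(self, state: dict) -> np.ndarray:
        M = np.tile(state["mu"], (self.P, 1))
        for si, d in enumerate(self.designs):
            if d.n_columns:
                M[:, si] += d.X @ state["beta"][si]
        return M

    def _g_vector(self, state: dict, si: int) -> np.ndarray:
        """Prior variance per design column of parameter si."""
        d = self.designs[si]
        g = np.empty(d.n_columns)
        for bi, blk in enumerate(d.blocks):
            g[blk.sl] = state["g"][si][bi]
        return g

    # -- engine contract ----------------------------------------------------

    def init(self, rng: np.random.Generator) -> dict:
        z0 = ndtri(self.theta_start)
        Z = z0[None, :] + rng.normal(0.0, 0.4, size=(self.P, self.S))
        state = {
            "Z": Z,
            "mu": z0 + rng.normal(0.0, 0.2, size=self.S),
            "Q": np.eye(self.S),
            "xi": np.full(self.S, 1.0),
            "beta": [np.zeros(d.n_columns) for d in self.designs],
            "g": [np.ones(len(d.blocks)) for d in self.designs],
            "ls_z": np.full((self.P, self.S), np.log(0.5)),
            "ls_xi": np.full(self.S, np.log(0.3)),
            "ls_shift": np.full(self.S, np.log(0.2)),
            "ls_scale": np.full(self.S, np.log(0.3)),
            "theta": None,
            "ll": None,
        }
        state["theta"] = ndtr(Z)
        state["ll"] = self._loglik_rows(state["theta"])
        return state

    def log_posterior(self, state: dict) -> float:
        return float(np.sum(state["ll"]))

    def sweep(self, state: dict, rng: np.random.Generator, iteration: int,
              adapting: bool) -> None:
        S, P = self.S, self.P
        xi = state["xi"]
        Q = state["Q"]
        Sigma = Q * np.outer(xi, xi)
        Lam = np.linalg.inv(Sigma)
        M = self._mean_matrix(state)
        step = adapt_step_size(iteration) if adapting else 0.0

        # 1) latent probit values z_ps: componentwise adaptive MH,
        #    vectorized across participants
        Z = state["Z"]
        theta = state["theta"]
        ll = state["ll"]
        for s in range(S):
            resid = Z - M
            h = resid @ Lam[:, s] - resid[:, s] * Lam[s, s]
            cond_mean = M[:, s] - h / Lam[s, s]
            cond_sd = 1.0 / np.sqrt(Lam[s, s])
            # random-walk proposal with per-(p,s) adapted scale
            scale = np.exp(state["ls_z"][:, s])
            prop = Z[:, s] + scale * rng.standard_normal(P)
            prop = np.clip(prop, -_Z_BOUND, _Z_BOUND)
            theta_prop = theta.copy()
            theta_prop[:, s] = ndtr(prop)
            ll_prop = self._loglik_rows(theta_prop)
            dlp = -0.5 / cond_sd**2 * (
                (prop - cond_mean) ** 2 - (Z[:, s] - cond_mean) ** 2
            )
            accept = np.log(rng.random(P)) < ll_prop - ll + dlp
            Z[accept, s] = prop[accept]
            theta[accept, s] = ndtr(prop[accept])
            ll = np.where(accept, ll_prop, ll)
            if adapting:
                state["ls_z"][:, s] += step * (accept.astype(float) - self.target)
            # independence proposal from the conditional prior: the prior
            # ratio cancels the proposal ratio, so acceptance is the
            # likelihood ratio alone; mixes weakly-informed components
            prop = cond_mean + cond_sd * rng.standard_normal(P)
            prop = np.clip(prop, -_Z_BOUND, _Z_BOUND)
            theta_prop = theta.copy()
            theta_prop[:, s] = ndtr(prop)
            ll_prop = self._loglik_rows(theta_prop)
            accept = np.log(rng.random(P)) < ll_prop - ll
            Z[accept, s] = prop[accept]
            theta[accept, s] = ndtr(prop[accept])
            ll = np.where(accept, ll_prop, ll)
        state["ll"] = ll

        # 1b) group moves against the hierarchical funnel, per parameter:
        #     a joint translation of (mu_s, z_.s) and a joint rescaling of
        #     the random-effect column delta_.s. Both are plain Metropolis
        #     moves on the exact target; the rescaling has Jacobian c^P.
        for s in range(S):
            # translation: residuals are unchanged, only prior(mu) and lik move
            t = np.exp(state["ls_shift"][s]) * rng.standard_normal()
            prop_col = Z[:, s] + t
            accepted = False
            if np.all(np.abs(prop_col) < _Z_BOUND):
                theta_prop = theta.copy()
                theta_prop[:, s] = ndtr(prop_col)
                ll_prop = self._loglik_rows(theta_prop)
                mu_new = state["mu"][s] + t
                dprior = -0.5 * (
                    (mu_new - self.mu0[s]) ** 2
                    - (state["mu"][s] - self.mu0[s]) ** 2
                ) / self.sd0[s] ** 2
                if np.log(rng.random()) < np.sum(ll_prop - ll) + dprior:
                    accepted = True
                    Z[:, s] = prop_col
                    theta[:, s] = theta_prop[:, s]
                    ll = ll_prop
                    state["mu"][s] = mu_new
                    M[:, s] += t
            if adapting:
                state["ls_shift"][s] += step * (float(accepted) - self.target)

            # rescale: z_.s -> m_.s + c * (z_.s - m_.s) at fixed Sigma
            c = np.exp(np.exp(state["ls_scale"][s]) * rng.standard_normal())
            resid = Z - M
            prop_col = M[:, s] + c * resid[:, s]
            accepted = False
            if np.all(np.abs(prop_col) < _Z_BOUND):
                resid_new = resid.copy()
                resid_new[:, s] = prop_col - M[:, s]
                theta_prop = theta.copy()
                theta_prop[:, s] = ndtr(prop_col)
                ll_prop = self._loglik_rows(theta_prop)
                dquad = -0.5 * (
                    np.sum((resid_new @ Lam) * resid_new)
                    - np.sum((resid @ Lam) * resid)
                )
                log_alpha = np.sum(ll_prop - ll) + dquad + P * np.log(c)
                if np.log(rng.random()) < log_alpha:
                    accepted = True
                    Z[:, s] = prop_col
                    theta[:, s] = theta_prop[:, s]
                    ll = ll_prop
            if adapting:
                state["ls_scale"][s] += step * (float(accepted) - self.target)

            # joint rescale of (xi_s, residual column): the random-effect
            # prior change and the Jacobian cancel, so acceptance is the
            # likelihood ratio (plus the uniform bounds on xi)
            c = np.exp(np.exp(state["ls_scale"][s]) * rng.standard_normal())
            xi_new = xi[s] * c
            prop_col = M[:, s] + c * (Z[:, s] - M[:, s])
            if (
                self.priors.xi_low < xi_new < self.priors.xi_high
                and np.all(np.abs(prop_col) < _Z_BOUND)
            ):
                theta_prop = theta.copy()
                theta_prop[:, s] = ndtr(prop_col)
                ll_prop = self._loglik_rows(theta_prop)
                # Jacobian c^(P+1) (column + xi) against prior factor c^-P
                if np.log(rng.random()) < np.sum(ll_prop - ll) + np.log(c):
                    Z[:, s] = prop_col
                    theta[:, s] = theta_prop[:, s]
                    ll = ll_prop
                    xi[s] = xi_new
                    # Sigma changed: refresh the precision used by all
                    # subsequent conditionals in this sweep
                    Sigma = Q * np.outer(xi, xi)
                    Lam = np.linalg.inv(Sigma)
        # 1c) joint translation of (beta_sk, z_.s) along each design column:
        #     residuals stay fixed, so only the likelihood and the slope
        #     prior enter the acceptance
        for si, d in enumerate(self.designs):
            for j in range(d.n_columns):
                t = 0.25 * rng.standard_normal()
                x_col = d.X[:, j]
                prop_col = Z[:, si] + t * x_col
                if not np.all(np.abs(prop_col) < _Z_BOUND):
                    continue
                theta_prop = theta.copy()
                theta_prop[:, si] = ndtr(prop_col)
                ll_prop = self._loglik_rows(theta_prop)
                g_j = self._g_vector(state, si)[j]
                b_old = state["beta"][si][j]
                b_new = b_old + t
                dprior = -0.5 * (b_new**2 - b_old**2) / g_j
                if np.log(rng.random()) < np.sum(ll_prop - ll) + dprior:
                    Z[:, si] = prop_col
                    theta[:, si] = theta_prop[:, si]
                    ll = ll_prop
                    state["beta"][si][j] = b_new
                    M[:, si] += t * x_col
        state["ll"] = ll

        # 2) group means mu: multivariate normal Gibbs
        pred = M - state["mu"][None, :]
        A = P * Lam + self.T0
        b = Lam @ (Z - pred).sum(axis=0) + self.T0 @ self.mu0
        cov = np.linalg.inv(A)
        state["mu"] = rng.multivariate_normal(cov @ b, cov, method="cholesky")
        M = self._mean_matrix(state)

        # 3) slopes / factor effects: normal Gibbs per parameter
        for si, d in enumerate(self.designs):
            if d.n_columns == 0:
                continue
            M0 = M.copy()
            M0[:, si] = state["mu"][si]
            r0 = (Z - M0) @ Lam[:, si]
            A = Lam[si, si] * (d.X.T @ d.X) + np.diag(1.0 / self._g_vector(state, si))
            b = d.X.T @ r0
            cov = np.linalg.inv(A)
            state["beta"][si] = rng.multivariate_normal(
                cov @ b, cov, method="cholesky"
            )
            M[:, si] = state["mu"][si] + d.X @ state["beta"][si]

        # 4) correlation-scale matrix Q: conjugate inverse-Wishart
        Dres = Z - M
        U = Dres / xi[None, :]
        scale_mat = self.V + U.T @ U
        scale_mat = 0.5 * (scale_mat + scale_mat.T)
        state["Q"] = stats.invwishart.rvs(
            df=self.df + P, scale=scale_mat, random_state=rng
        )
        Q = state["Q"] = np.atleast_2d(state["Q"])

        # 5) scaling factors xi_s: bounded random-walk MH
        Qinv = np.linalg.inv(Q)

        def xi_logdens(xi_vec: np.ndarray) -> float:
            Uv = Dres / xi_vec[None, :]
            quad = float(np.sum((Uv @ Qinv) * Uv))
            return -P * float(np.sum(np.log(xi_vec))) - 0.5 * quad

        cur = xi_logdens(xi)
        for s in range(S):
            prop = xi.copy()
            prop[s] = xi[s] + np.exp(state["ls_xi"][s]) * rng.standard_normal()
            accepted = False
            if self.priors.xi_low < prop[s] < self.priors.xi_high:
                new = xi_logdens(prop)
                if np.log(rng.random()) < new - cur:
                    xi[s] = prop[s]
                    cur = new
                    accepted = True
            if adapting:
                state["ls_xi"][s] += step * (float(accepted) - self.target)
        state["xi"] = xi

        # 6) slope variances g: conjugate inverse-gamma per block
        if not self.priors.fix_g:
            v2 = self.priors.v_slope**2
            for si, d in enumerate(self.designs):
                for bi, blk in enumerate(d.blocks):
                    beta_blk = state["beta"][si][blk.sl]
                    shape = 0.5 + 0.5 * beta_blk.size
                    rate = 0.5 * v2 + 0.5 * float(beta_blk @ beta_blk)
                    state["g"][si][bi] = 1.0 / rng.gamma(shape, 1.0 / rate)

    def record(self, state: dict) -> np.ndarray:
        xi = state["xi"]
        Q = state["Q"]
        sig = xi * np.sqrt(np.diag(Q))
        out = [ndtr(state["mu"]), state["mu"], sig, xi]
        rho = []
        for i in range(self.S):
            for j in range(i + 1, self.S):
                rho.append(Q[i, j] / np.sqrt(Q[i, i] * Q[j, j]))
        out.append(np.asarray(rho))
        betas = []
        for si, d in enumerate(self.designs):
            for blk in d.blocks:
                b = state["beta"][si][blk.sl]
                betas.extend(b.tolist())
                if blk.kind == "continuous":
                    betas.append(float(b[0]) / blk.sd)
        out.append(np.asarray(betas))
        out.append(state["theta"].T.reshape(-1))  # theta_{param}[participant]
        return np.concatenate(out)


@dataclass
class TraitFit:
    """Fitted latent-trait MPT model."""

    model: MptModel
    data: FrequencyTable
    draws: PosteriorDraws
    priors: TraitPriors
    spec: PredictorSpec
    designs: dict[str, ParameterDesign]
    covariates: pd.DataFrame | None
    convergence: ConvergenceReport

    kind: str = "trait"

    @property
    def parameters(self) -> tuple[str, ...]:
        return self.model.parameters

    def summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        sel = [n for n in self.draws.names if not n.startswith("theta_")]
        return summarize_draws(self.draws, probs, names=sel)

    def theta_draws(self, parameter: str) -> np.ndarray:
        """Individual-parameter draws, shape (P, n_draws) pooled over chains."""
        names = self.draws.matching(f"theta_{parameter}[")
        return np.stack([self.draws.flat(n) for n in names])

    def theta_posterior_mean(self) -> np.ndarray:
        out = np.empty((self.data.n_participants, len(self.parameters)))
        for j, p in enumerate(self.parameters):
            out[:, j] = self.theta_draws(p).mean(axis=1)
        return out


def _check_convergence(draws: PosteriorDraws, threshold: float = 1.05
                       ) -> ConvergenceReport:
    conv = gelman_rubin(draws)
    if not conv.converged(threshold):
        bad = conv.table[
            (~conv.table["degenerate"]) & (conv.table["rhat"] >= threshold)
        ]
        worst = bad["rhat"].sort_values(ascending=False).head(5)
        warnings.warn(
            "MCMC may not have converged: "
            f"{len(bad)} parameters with R-hat >= {threshold} "
            f"(worst: {worst.to_dict()}); consider extending the run",
            stacklevel=3,
        )
    return conv


def fit_trait(
    model: MptModel,
    data: FrequencyTable,
    covariates: pd.DataFrame | None = None,
    spec: PredictorSpec | None = None,
    priors: TraitPriors | None = None,
    settings: McmcSettings | None = None,
) -> TraitFit:
    """Fit the latent-trait MPT model by MCMC.

    ``data`` columns are matched to the model's categories by label.
    Returns a :class:`TraitFit`; if any split-chain R-hat is >= 1.05 a
    prominent warning is emitted (the result is still returned).
    """
    priors = priors or TraitPriors()
    settings = settings or McmcSettings()
    spec = spec or PredictorSpec()
    data = data.aligned_to(model)
    if spec.assignments and covariates is not None and len(covariates) != data.n_participants:
        raise ValueError("covariate rows must align with participants")
    designs = build_design(covariates, spec, model.parameters)
    compiled = compile_model(model)
    kernel = _TraitKernel(compiled, data, designs, priors,
                          settings.target_acceptance)
    draws = run_chains(kernel, settings)
    conv = _check_convergence(draws)
    return TraitFit(model, data, draws, priors, spec, designs, covariates, conv)


def sample_prior_predictive_priors(
    priors: TraitPriors, S: int = 2, n: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Sample the priors implied for group means, SDs, and correlations.

    Draws (mu, Q, xi) from their priors and returns the implied
    probability-scale group mean Phi(mu_s), probit-scale SD
    sigma_s = xi_s * sqrt(Q_ss), and the correlation rho_12 (when S >= 2);
    the data behind prior-predictive histograms.
    """
    rng = np.random.default_rng(seed)
    mu0, sd0, V, df = priors.resolved(S)
    mu = rng.normal(mu0, sd0, size=(n, S))
    xi = rng.uniform(priors.xi_low, priors.xi_high, size=(n, S))
    Qs = stats.invwishart.rvs(df=df, scale=V, size=n, random_state=rng)
    Qs = Qs.reshape(n, S, S)
    diag = np.einsum("nii->ni", Qs)
    out = {}
    for s in range(S):
        out[f"prob_mean_{s}"] = ndtr(mu[:, s])
        out[f"sigma_{s}"] = xi[:, s] * np.sqrt(diag[:, s])
    if S >= 2:
        out["rho_01"] = Qs[:, 0, 1] / np.sqrt(Qs[:, 0, 0] * Qs[:, 1, 1])
    return pd.DataFrame(out)
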