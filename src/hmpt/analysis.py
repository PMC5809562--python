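"""Post-fit analyses: transformed parameters, probit-scale moment mapping,
between-subjects comparisons, factor-level group means, and covariate
correlations with a sampling-error-corrected population posterior.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import hyp2f1, ndtr
from numpy.polynomial.hermite_e import hermegauss

__all__ = [
    "TransformExpression",
    "CorrelationSummary",
    "transform_draws",
    "probit_inverse",
    "between_subjects_compare",
    "group_means_by_factor",
    "covariate_correlations",
    "population_correlation",
    "PopulationCorrelation",
]

_EXPR_TOKEN = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_EXPR_ALLOWED = re.compile(r"^[A-Za-z0-9_+\-*/(). ]+$")


@dataclass(frozen=True)
class TransformExpression:
    """A named arithmetic transform of fitted parameters, e.g.
    ``deltaDd = D - d`` (operators ``+ - * /`` and parentheses)."""

    name: str
    expression: str

    @staticmethod
    def parse(text: str) -> "TransformExpression":
        name, eq, expr = text.partition("=")
        if not eq:
            raise ValueError(f"transform must be 'name = expression', got {text!r}")
        return TransformExpression(name.strip(), expr.strip())

    def variables(self) -> list[str]:
        return sorted(set(_EXPR_TOKEN.findall(self.expression)))

    def evaluate(self, env: dict[str, np.ndarray]) -> np.ndarray:
        if not _EXPR_ALLOWED.match(self.expression):
            raise ValueError(f"disallowed characters in {self.expression!r}")
        missing = [v for v in self.variables() if v not in env]
        if missing:
            raise KeyError(f"unknown parameters in transform: {missing}")
        return eval(self.expression, {"__builtins__": {}}, env)  # noqa: S307


def transform_draws(fit, expressions, level: str = "group") -> pd.DataFrame:
    """Evaluate transforms per posterior draw and summarize.

    ``level="group"`` binds parameter names to probability-scale group
    means; ``level="individual"`` returns one row per (transform,
    participant). Draws where a division by zero occurs are excluded, with
    the count reported in the ``n_excluded`` column. The Bayesian p value
    is the fraction of draws below zero.
    """
    if isinstance(expressions, (str, TransformExpression)):
        expressions = [expressions]
    expressions = [
        TransformExpression.parse(e) if isinstance(e, str) else e
        for e in expressions
    ]
    rows = []
    for expr in expressions:
        if level == "group":
            env = {p: fit.draws.flat(f"mean_{p}") for p in fit.parameters}
            arrays = {"": _eval_safe(expr, env)}
        elif level == "individual":
            arrays = {}
            per_param = {p: fit.theta_draws(p) for p in fit.parameters}
            for i, rid in enumerate(fit.data.row_ids):
                env = {p: per_param[p][i] for p in fit.parameters}
                arrays[str(rid)] = _eval_safe(expr, env)
        else:
            raise ValueError("level must be 'group' or 'individual'")
        for key, (vals, n_excl) in arrays.items():
            rows.append(
                {
                    "name": expr.name if not key else f"{expr.name}[{key}]",
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "q2.5%": float(np.quantile(vals, 0.025)),
                    "q50%": float(np.quantile(vals, 0.5)),
                    "q97.5%": float(np.quantile(vals, 0.975)),
                    "p_below_zero": float(np.mean(vals < 0)),
                    "n_excluded": n_excl,
                }
            )
    return pd.DataFrame(rows).set_index("name")


def _eval_safe(expr: TransformExpression, env: dict[str, np.ndarray]):
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.asarray(expr.evaluate(env), dtype=float)
    bad = ~np.isfinite(vals)
    return vals[~bad], int(bad.sum())


_HERM_X, _HERM_W = hermegauss(80)  # probabilists' Hermite nodes: E[f(Z)]


def probit_inverse(mu: float, sigma: float) -> tuple[float, float]:
    """Implied probability-scale mean and SD of Phi(X), X ~ N(mu, sigma^2).

    The mean has the closed form Phi(mu / sqrt(1 + sigma^2)); the second
    moment E[Phi(X)^2] is evaluated by Gauss-Hermite quadrature.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    mean = float(ndtr(mu / np.sqrt(1.0 + sigma**2)))
    if sigma == 0:
        return mean, 0.0
    vals = ndtr(mu + sigma * _HERM_X) ** 2
    second = float(np.sum(_HERM_W * vals) / np.sqrt(2 * np.pi))
    var = max(second - mean**2, 0.0)
    return mean, float(np.sqrt(var))


def between_subjects_compare(
    fit1, fit2, parameter: str, stat: str = "x-y"
) -> pd.DataFrame:
    """Compare a group-mean parameter across two independently fitted groups.

    Per draw, ``stat`` is evaluated with ``x`` = group-1 probability-scale
    mean and ``y`` = group 2's (draws paired by index after truncating to
    the common length). Reports the posterior mean, 95% CI, and the
    Bayesian p value p_B = fraction of draws with x < y.
    """
    x = fit1.draws.flat(f"mean_{parameter}")
    y = fit2.draws.flat(f"mean_{parameter}")
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    expr = TransformExpression("stat", stat)
    vals, n_excl = _eval_safe(expr, {"x": x, "y": y})
    return pd.DataFrame(
        [
            {
                "parameter": parameter,
                "stat": stat,
                "mean": float(np.mean(vals)),
                "q2.5%": float(np.quantile(vals, 0.025)),
                "q97.5%": float(np.quantile(vals, 0.975)),
                "p_B": float(np.mean(x < y)),
                "n_excluded": n_excl,
            }
        ]
    ).set_index("parameter")


def group_means_by_factor(fit, factor_name: str) -> pd.DataFrame:
    """Per-level probability-scale group means Phi(mu_s + eta_sl).

    Works for factors fitted as fixed (sum-to-zero coded; the omitted
    level's effect is minus the sum of the others) or random effects.
    """
    from .mcmc import gelman_rubin

    rows = []
    level_draws = []
    names = []
    found = False
    for p in fit.parameters:
        design = fit.designs[p]
        for blk in design.blocks:
            if blk.covariate != factor_name or blk.kind == "continuous":
                continue
            found = True
            mu = fit.draws.get(f"mu_{p}")  # (chains, n)
            effs = [fit.draws.get(f"beta_{p}_{c}") for c in blk.columns]
            if blk.kind == "fixed_factor":
                effs = effs + [-sum(effs)]
            for lev, eta in zip(blk.levels, effs):
                draws = ndtr(mu + eta)
                level_draws.append(draws)
                names.append((p, lev))
    if not found:
        raise KeyError(f"factor {factor_name!r} was not fitted as an effect")
    arr = np.stack(level_draws, axis=-1)
    conv = gelman_rubin(arr, names=[f"{p}:{l}" for p, l in names])
    for j, (p, lev) in enumerate(names):
        d = arr[:, :, j].reshape(-1)
        rows.append(
            {
                "parameter": p,
                "level": lev,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "q2.5%": float(np.quantile(d, 0.025)),
                "q97.5%": float(np.quantile(d, 0.975)),
                "rhat": float(conv.table.iloc[j]["rhat"]),
            }
        )
    return pd.DataFrame(rows).set_index(["parameter", "level"])


@dataclass
class CorrelationSummary:
    """Posterior draws of sample correlations r and, after
    :func:`population_correlation`, the density of the population rho."""

    r_draws: dict[tuple[str, str], np.ndarray]
    n: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for (p, cov), r in self.r_draws.items():
            rows.append(
                {
                    "parameter": p,
                    "covariate": cov,
                    "r_mean": float(r.mean()),
                    "r_q2.5%": float(np.quantile(r, 0.025)),
                    "r_q97.5%": float(np.quantile(r, 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index(["parameter", "covariate"])


def covariate_correlations(
    fit, covariates: pd.DataFrame, cor_probit: bool = False
) -> CorrelationSummary:
    """Per-draw Pearson correlations between covariates and individual
    parameters (probability scale; probit scale with ``cor_probit``)."""
    from scipy.special import ndtri

    P = fit.data.n_participants
    if len(covariates) != P:
        raise ValueError("covariate rows must align with participants")
    numeric = [
        c for c in covariates.columns
        if np.issubdtype(covariates[c].dtype, np.number)
    ]
    out: dict[tuple[str, str], np.ndarray] = {}
    for cov in numeric:
        x = covariates[cov].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValueError(f"covariate {cov!r} is constant")
        xc = x - x.mean()
        for p in fit.parameters:
            th = fit.theta_draws(p)  # (P, n_draws)
            vals = ndtri(np.clip(th, 1e-12, 1 - 1e-12)) if cor_probit else th
            vc = vals - vals.mean(axis=0, keepdims=True)
            num = xc @ vc
            den = np.sqrt((xc @ xc) * np.sum(vc * vc, axis=0))
            out[(p, cov)] = num / np.maximum(den, 1e-300)
    return CorrelationSummary(out, P)


def _log_density_r_given_rho(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Log sampling density of the Pearson correlation r for a bivariate
    normal sample of size n with population correlation rho (exact form,
    via the Gaussian hypergeometric function)."""
    from scipy.special import gammaln

    rho = np.asarray(rho, dtype=float)
    logc = (
        np.log(n - 2.0)
        + gammaln(n - 1.0)
        - 0.5 * np.log(2 * np.pi)
        - gammaln(n - 0.5)
    )
    val = (
        logc
        + 0.5 * (n - 1.0) * np.log1p(-(rho**2))
        + 0.5 * (n - 4.0) * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
    )
    val += np.log(hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (rho * r + 1.0)))
    return val


@dataclass(frozen=True)
class PopulationCorrelation:
    """Averaged posterior of the population correlation on a rho grid."""

    rho: np.ndarray
    density: np.ndarray
    mean: float
    median: float
    ci_low: float
    ci_high: float


def population_correlation(
    r_draws: np.ndarray, n: int, grid_size: int = 2001
) -> PopulationCorrelation:
    """Sampling-error-corrected posterior of the population correlation.

    For each posterior draw of the sample correlation r, the analytic
    posterior density of rho given (r, n) under a uniform prior on (-1, 1)
    is evaluated on a grid; the densities are averaged over draws and the
    95% CI is read off the averaged distribution. The averaged posterior is
    wider than the spread of the r draws alone because it adds the
    sampling error of a correlation at sample size n.
    """
    if n < 4:
        raise ValueError("need at least 4 participants")
    r_draws = np.asarray(r_draws, dtype=float)
    r_draws = np.clip(r_draws, -1 + 1e-6, 1 - 1e-6)  # eps-shrinkage at |r|=1
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, grid_size)
    dens = np.zeros(grid_size)
    for r in np.atleast_1d(r_draws):
        logd = _log_density_r_given_rho(float(r), rho, n)
        d = np.exp(logd - logd.max())
        d /= np.trapezoid(d, rho)
        dens += d
    dens /= len(np.atleast_1d(r_draws))
    dens /= np.trapezoid(dens, rho)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(rho))])
    cdf /= cdf[-1]
    mean = float(np.trapezoid(rho * dens, rho))
    lo = float(np.interp(0.025, cdf, rho))
    hi = float(np.interp(0.975, cdf, rho))
    med = float(np.interp(0.5, cdf, rho))
    return PopulationCorrelation(rho, dens, mean, med, lo, hi)
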