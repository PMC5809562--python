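"""Posterior-predictive model checking and DIC.

Model fit is assessed by comparing the observed frequencies against data
simulated from the posterior. Two discrepancy statistics are used: T1
measures the distance between observed (or predicted) and expected *mean*
frequencies in Pearson chi-square form; T2 measures the summed absolute
differences between observed (or predicted) and expected cross-category
*covariances*, standardized by the expected standard deviations. The
posterior-predictive p value (PPP) is the proportion of posterior draws
with T_obs < T_pred; values near zero flag misfit.

Expected moments per draw are computed analytically from the multinomial
mean/covariance formulas conditional on the draw's individual parameters
(no nested simulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .likelihood import (
    FrequencyTable,
    compile_model,
    category_probabilities,
    log_likelihood,
)

__all__ = [
    "PppResult",
    "posterior_predictive_samples",
    "T1_statistic",
    "T2_statistic",
    "expected_moments",
    "ppp",
    "dic",
]


def T1_statistic(freqs: FrequencyTable | np.ndarray, expected_mean: np.ndarray) -> float:
    """Pearson-form distance between observed and expected mean frequencies.

    ``sum_k (mean_obs_k - e_k)^2 / e_k`` with the observed mean taken across
    participants. Categories with zero expectation are excluded with a
    warning.
    """
    counts = freqs.counts if isinstance(freqs, FrequencyTable) else np.asarray(freqs)
    mean_obs = counts.mean(axis=0)
    e = np.asarray(expected_mean, dtype=float)
    keep = e > 0
    if not np.all(keep):
        warnings.warn("categories with zero expected frequency excluded from T1",
                      stacklevel=2)
    return float(np.sum((mean_obs[keep] - e[keep]) ** 2 / e[keep]))


def T2_statistic(
    freqs: FrequencyTable | np.ndarray,
    expected_cov: np.ndarray,
    expected_sd: np.ndarray,
) -> float:
    """Covariance discrepancy: sum over pairs k < l of
    ``|cov_obs(k,l) - cov_exp(k,l)| / (sd_k * sd_l)``.

    Observed covariances are taken across participants; the sum runs over
    off-diagonal pairs only (the statistic targets *co*-variances).
    """
    counts = freqs.counts if isinstance(freqs, FrequencyTable) else np.asarray(freqs)
    if counts.shape[0] < 2:
        raise ValueError("covariances need at least 2 participants")
    sd = np.asarray(expected_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("expected standard deviations must be positive")
    cov_obs = np.cov(counts.T, ddof=1)
    diff = np.abs(cov_obs - np.asarray(expected_cov, dtype=float))
    denom = np.outer(sd, sd)
    iu = np.triu_indices(counts.shape[1], k=1)
    return float(np.sum(diff[iu] / denom[iu]))


def expected_moments(theta: np.ndarray, data: FrequencyTable, compiled) -> tuple:
    """Analytic expected mean vector and K x K covariance of individual
    frequencies, conditional on the P x S parameter matrix ``theta``.

    Within a tree, counts are multinomial per participant:
    Cov(n_k, n_l | theta_p) = n_t (pi_k 1{k=l} - pi_k pi_l); across trees
    counts are independent. The population covariance adds the spread of
    the per-participant expectations across the fixed set of participants;
    both pieces use the ddof=1 convention so that the sample covariance of
    an observed table is unbiased for the returned matrix.
    """
    probs = category_probabilities(theta, compiled)  # (P, K)
    trees = compiled.model.trees
    tree_idx = compiled.cat_tree_index
    totals = data.tree_totals()  # (P, T) in data tree order
    order = [data.trees.index(t) for t in trees]
    n_pt = totals[:, order]  # (P, T) aligned to model tree order
    n_cat = n_pt[:, tree_idx]  # (P, K)
    e = n_cat * probs  # expected counts per participant
    mean_exp = e.mean(axis=0)

    P, K = probs.shape
    within = np.zeros((K, K))
    same_tree = tree_idx[:, None] == tree_idx[None, :]
    # average multinomial covariance across participants
    for p in range(P):
        pi = probs[p]
        c = -np.outer(pi, pi) * same_tree
        np.fill_diagonal(c, pi * (1 - pi))
        within += n_cat[p][None, :] * c / P
    between = np.cov(e.T, ddof=1) if P > 1 else np.zeros((K, K))
    cov_exp = within + between
    sd_exp = np.sqrt(np.maximum(np.diag(cov_exp), 1e-12))
    return mean_exp, cov_exp, sd_exp


def _simulate_table(
    theta: np.ndarray, data: FrequencyTable, compiled, rng: np.random.Generator
) -> np.ndarray:
    """One predictive P x K table with the observed per-tree totals."""
    probs = category_probabilities(theta, compiled)
    trees = compiled.model.trees
    tree_idx = compiled.cat_tree_index
    totals = data.tree_totals()
    order = [data.trees.index(t) for t in trees]
    n_pt = totals[:, order]
    out = np.zeros_like(data.counts, dtype=np.int64)
    for ti in range(len(trees)):
        cols = np.flatnonzero(tree_idx == ti)
        pi = probs[:, cols]
        pi = pi / pi.sum(axis=1, keepdims=True)
        for p in range(data.n_participants):
            out[p, cols] = rng.multinomial(int(n_pt[p, ti]), pi[p])
    return out


def _theta_matrix_draws(fit, M: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample M retained draws of the P x S individual-parameter matrix."""
    total = fit.draws.n_chains * fit.draws.n_retained
    replace = M > total
    idx = rng.choice(total, size=M, replace=replace)
    P = fit.data.n_participants
    S = len(fit.parameters)
    theta = np.empty((M, P, S))
    for j, p in enumerate(fit.parameters):
        cols = fit.theta_draws(p)  # (P, total)
        theta[:, :, j] = cols[:, idx].T
    return theta


def posterior_predictive_samples(
    fit, M: int, level: str = "individual", seed: int = 0
) -> list[np.ndarray]:
    """M simulated frequency tables from the fitted model's posterior.

    ``level="individual"`` uses each draw's individual parameters;
    ``level="group"`` draws fresh participants from the draw's population
    distribution (latent-trait: MVN on the probit scale; beta-MPT:
    independent betas). Per-tree totals always match the observed data.
    """
    rng = np.random.default_rng(seed)
    compiled = compile_model(fit.model)
    thetas = _theta_matrix_draws(fit, M, rng)
    tables = []
    for m in range(M):
        theta = thetas[m]
        if level == "group":
            theta = _group_level_theta(fit, m, rng, theta.shape[0])
        tables.append(_simulate_table(theta, fit.data, compiled, rng))
    return tables


def _group_level_theta(fit, m: int, rng: np.random.Generator, P: int) -> np.ndarray:
    from scipy.special import ndtr

    S = len(fit.parameters)
    if fit.kind == "trait":
        mu = np.array([fit.draws.flat(f"mu_{p}")[m] for p in fit.parameters])
        sig = np.array([fit.draws.flat(f"sigma_{p}")[m] for p in fit.parameters])
        corr = np.eye(S)
        for i, p in enumerate(fit.parameters):
            for j, q in enumerate(fit.parameters[i + 1:], start=i + 1):
                corr[i, j] = corr[j, i] = fit.draws.flat(f"rho_{p}_{q}")[m]
        cov = corr * np.outer(sig, sig)
        z = rng.multivariate_normal(mu, cov, size=P)
        return ndtr(z)
    alpha = np.array([fit.draws.flat(f"alpha_{p}")[m] for p in fit.parameters])
    beta = np.array([fit.draws.flat(f"beta_{p}")[m] for p in fit.parameters])
    return rng.beta(alpha, beta, size=(P, S))


@dataclass
class PppResult:
    """Observed/predicted T1 and T2 distributions and PPP values."""

    T1_obs: np.ndarray
    T1_pred: np.ndarray
    T2_obs: np.ndarray
    T2_pred: np.ndarray
    ppp_T1: float
    ppp_T2: float
    individual_ppp: np.ndarray


def ppp(fit, M: int = 1000, seed: int = 0) -> PppResult:
    """Posterior-predictive p values for the T1 and T2 statistics.

    For each of M posterior draws, expected moments are computed
    analytically from that draw's individual parameters; T_obs evaluates
    the observed table against them, T_pred a table simulated under the
    draw. PPP = mean(T_obs < T_pred). ``individual_ppp`` applies the T1
    discrepancy per participant row.
    """
    rng = np.random.default_rng(seed)
    compiled = compile_model(fit.model)
    data = fit.data
    thetas = _theta_matrix_draws(fit, M, rng)
    P = data.n_participants
    t1o = np.empty(M)
    t1p = np.empty(M)
    t2o = np.empty(M)
    t2p = np.empty(M)
    ind_obs = np.empty((M, P))
    ind_pred = np.empty((M, P))
    for m in range(M):
        theta = thetas[m]
        mean_exp, cov_exp, sd_exp = expected_moments(theta, data, compiled)
        sim = _simulate_table(theta, data, compiled, rng)
        t1o[m] = T1_statistic(data.counts, mean_exp)
        t1p[m] = T1_statistic(sim, mean_exp)
        t2o[m] = T2_statistic(data.counts, cov_exp, sd_exp)
        t2p[m] = T2_statistic(sim, cov_exp, sd_exp)
        # per-participant T1 against that participant's own expectation
        trees = compiled.model.trees
        totals = data.tree_totals()
        order = [data.trees.index(t) for t in trees]
        n_cat = totals[:, order][:, compiled.cat_tree_index]
        e_p = category_probabilities(theta, compiled) * n_cat
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_stat = np.where(e_p > 0, (data.counts - e_p) ** 2 / e_p, 0.0)
            pred_stat = np.where(e_p > 0, (sim - e_p) ** 2 / e_p, 0.0)
        ind_obs[m] = obs_stat.sum(axis=1)
        ind_pred[m] = pred_stat.sum(axis=1)
    return PppResult(
        T1_obs=t1o,
        T1_pred=t1p,
        T2_obs=t2o,
        T2_pred=t2p,
        ppp_T1=float(np.mean(t1o < t1p)),
        ppp_T2=float(np.mean(t2o < t2p)),
        individual_ppp=(ind_obs < ind_pred).mean(axis=0),
    )


def dic(fit) -> tuple[float, float, float]:
    """Deviance information criterion with conditional (individual-theta)
    likelihood focus.

    Returns (DIC, pD, Dbar) where D = -2 log L(theta), Dbar is the
    posterior mean deviance, pD = Dbar - D(posterior mean of theta), and
    DIC = Dbar + pD.
    """
    compiled = compile_model(fit.model)
    data = fit.data
    total = fit.draws.n_chains * fit.draws.n_retained
    P = data.n_participants
    S = len(fit.parameters)
    theta_all = np.empty((total, P, S))
    for j, p in enumerate(fit.parameters):
        theta_all[:, :, j] = fit.theta_draws(p).T
    dev = np.empty(total)
    for m in range(total):
        dev[m] = -2.0 * log_likelihood(theta_all[m], data, compiled)
    dbar = float(dev.mean())
    theta_bar = theta_all.mean(axis=0)
    d_hat = -2.0 * log_likelihood(theta_bar, data, compiled)
    pd_ = dbar - d_hat
    return dbar + pd_, pd_, dbar
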