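"""Synthetic-data generation and parameter-recovery simulation.

Three generators mirror the three levels at which MPT data can be
specified: a fixed participant x parameter matrix (``gen_mpt``), a
latent-trait population — probit-normal with optional covariate slopes —
(``gen_trait_mpt``), and independent beta populations (``gen_beta_mpt``).
``recovery_simulation`` wraps generate-and-fit replications of the
latent-trait model and aggregates posterior means, credible-interval
coverage and slope zero-exclusion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .beta import moments_to_shapes
from .eqn import (
    MptModel,
    apply_restrictions,
    parse_eqn,
    parse_restrictions,
    two_htsm_eqn,
    two_htsm_restrictions,
)
from .likelihood import FrequencyTable, compile_model, category_probabilities
from .mcmc import McmcSettings
from .trait import PredictorSpec, TraitPriors, fit_trait

__all__ = [
    "TraitPopulationSpec",
    "SimulationReport",
    "gen_mpt",
    "gen_trait_mpt",
    "gen_beta_mpt",
    "recovery_simulation",
    "table2_design",
    "restricted_2htsm",
]


def gen_mpt(
    theta: np.ndarray,
    model: MptModel,
    items_per_tree: dict[str, int],
    seed: int = 0,
) -> FrequencyTable:
    """Multinomial response frequencies for a fixed P x S theta matrix."""
    compiled = compile_model(model)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    for t in model.trees:
        if items_per_tree.get(t, 0) <= 0:
            raise ValueError(f"items_per_tree[{t!r}] must be positive")
    rng = np.random.default_rng(seed)
    probs = category_probabilities(theta, compiled)
    P = theta.shape[0]
    K = probs.shape[1]
    counts = np.zeros((P, K), dtype=np.int64)
    tree_idx = compiled.cat_tree_index
    for ti, tree in enumerate(model.trees):
        cols = np.flatnonzero(tree_idx == ti)
        pi = probs[:, cols]
        pi = pi / pi.sum(axis=1, keepdims=True)
        n = int(items_per_tree[tree])
        for p in range(P):
            counts[p, cols] = rng.multinomial(n, pi[p])
    return FrequencyTable(
        counts, list(model.category_labels), dict(model.categories)
    )


@dataclass(frozen=True)
class TraitPopulationSpec:
    """Probit-scale population for the latent-trait generator.

    ``mu_probit`` and ``sigma_probit`` are per-parameter (model parameter
    order); ``correlation`` defaults to the identity; ``slopes`` maps
    parameter names to standardized regression weights of a standard-normal
    covariate.
    """

    mu_probit: np.ndarray
    sigma_probit: np.ndarray
    correlation: np.ndarray | None = None
    slopes: dict[str, float] = field(default_factory=dict)

    def cov(self) -> np.ndarray:
        sig = np.asarray(self.sigma_probit, dtype=float)
        S = len(sig)
        R = np.eye(S) if self.correlation is None else np.asarray(self.correlation)
        if R.shape != (S, S) or not np.allclose(R, R.T) or not np.allclose(
            np.diag(R), 1.0
        ):
            raise ValueError("correlation must be symmetric with unit diagonal")
        if np.any(np.linalg.eigvalsh(R) < -1e-10):
            raise ValueError("correlation matrix must be positive semidefinite")
        return R * np.outer(sig, sig)

    @staticmethod
    def from_probability_scale(
        mean_prob: np.ndarray, sd_prob: np.ndarray, **kw
    ) -> "TraitPopulationSpec":
        """Convenience converter: probability-scale (mean, SD) to probit
        (mu, sigma) by inverting the implied-moment map numerically."""
        from scipy.optimize import brentq

        from .analysis import probit_inverse

        mu = np.empty(len(mean_prob))
        sig = np.empty(len(mean_prob))
        for i, (m, s) in enumerate(zip(mean_prob, sd_prob)):
            if s == 0:
                mu[i], sig[i] = ndtri(m), 0.0
                continue

            def sd_gap(sigma: float) -> float:
                mu_i = ndtri(m) * np.sqrt(1.0 + sigma**2)
                return probit_inverse(mu_i, sigma)[1] - s

            sig[i] = brentq(sd_gap, 1e-6, 25.0)
            mu[i] = ndtri(m) * np.sqrt(1.0 + sig[i] ** 2)
        return TraitPopulationSpec(mu, sig, **kw)


def gen_trait_mpt(
    P: int,
    items_per_tree: dict[str, int],
    spec: TraitPopulationSpec,
    model: MptModel,
    seed: int = 0,
) -> tuple[FrequencyTable, np.ndarray, pd.DataFrame | None]:
    """Simulate a latent-trait population and its response frequencies.

    Returns (frequency table, true P x S theta matrix, covariate table or
    None). Probit values are mu + x_p * slope + delta_p with delta_p ~
    MVN(0, diag(sigma) R diag(sigma)) and x ~ N(0, 1) when slopes are set.
    """
    mu = np.asarray(spec.mu_probit, dtype=float)
    if len(mu) != model.n_parameters:
        raise ValueError("spec dimension does not match the model")
    rng = np.random.default_rng(seed)
    cov = spec.cov()
    Z = mu[None, :] + rng.multivariate_normal(np.zeros(len(mu)), cov, size=P)
    covariates = None
    if spec.slopes:
        unknown = set(spec.slopes) - set(model.parameters)
        if unknown:
            raise KeyError(f"slopes reference unknown parameters: {sorted(unknown)}")
        x = rng.standard_normal(P)
        for name, b in spec.slopes.items():
            Z[:, model.parameters.index(name)] += b * x
        covariates = pd.DataFrame({"x": x})
    theta = ndtr(Z)
    table = gen_mpt(theta, model, items_per_tree, seed=int(rng.integers(2**31)))
    return table, theta, covariates


def gen_beta_mpt(
    P: int,
    items_per_tree: dict[str, int],
    mean: np.ndarray,
    sd: np.ndarray,
    model: MptModel,
    seed: int = 0,
) -> tuple[FrequencyTable, np.ndarray]:
    """Simulate a beta-MPT population: theta_ps ~ Beta(alpha_s, beta_s)
    with shapes matched to the requested probability-scale moments."""
    alpha, beta = moments_to_shapes(np.asarray(mean, float), np.asarray(sd, float))
    rng = np.random.default_rng(seed)
    theta = rng.beta(alpha, beta, size=(P, model.n_parameters))
    table = gen_mpt(theta, model, items_per_tree, seed=int(rng.integers(2**31)))
    return table, theta


# ---------------------------------------------------------------------------
# The 2HTSM recovery-simulation design
# ---------------------------------------------------------------------------

def restricted_2htsm() -> MptModel:
    """The identifiable 4-parameter 2HTSM (D_1=D_2=D_3, d_1=d_2, a=g)."""
    model = parse_eqn(two_htsm_eqn())
    r = parse_restrictions(two_htsm_restrictions(), model)
    return apply_restrictions(model, r)


def table2_design() -> tuple[MptModel, TraitPopulationSpec, dict[str, int], int]:
    """The recovery-study design: 50 participants, 16 items per source tree
    and 32 new items; probit means (sd) a = 0.3 (0.6), b = -0.1 (0.5),
    d = 0.6 (1.0), D = probit(0.62) ~ 0.31 (0.2); standardized slopes
    beta^D = -0.3 and beta^d = 0.5 on one standard-normal covariate.

    Returns (model, population spec, items per tree, P). Spec vectors are
    in the model's (alphabetical) parameter order D_1, a, b, d_1.
    """
    model = restricted_2htsm()
    order = model.parameters  # ('D_1', 'a', 'b', 'd_1')
    mu = {"a": 0.3, "b": -0.1, "d_1": 0.6, "D_1": float(ndtri(0.62))}
    sd = {"a": 0.6, "b": 0.5, "d_1": 1.0, "D_1": 0.2}
    spec = TraitPopulationSpec(
        mu_probit=np.array([mu[p] for p in order]),
        sigma_probit=np.array([sd[p] for p in order]),
        slopes={"D_1": -0.3, "d_1": 0.5},
    )
    items = {"E": 16, "U": 16, "N": 32}
    return model, spec, items, 50


@dataclass
class SimulationReport:
    """Aggregated parameter-recovery results across replications.

    One row per reported quantity: the data-generating value, the mean
    posterior mean across replications, mean 2.5%/97.5% CI bounds, mean
    absolute bias |posterior mean - truth|, 95%-CI coverage in percent,
    and (slopes only) the percentage of replications whose 95% CI excludes
    zero.
    """

    table: pd.DataFrame
    records: pd.DataFrame  # per-replication rows for reanalysis
    n_replications: int
    n_excluded: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"recovery simulation, {self.n_replications} replications "
            f"({self.n_excluded} excluded)\n" + self.table.to_string()
        )


def recovery_simulation(
    model: MptModel,
    spec: TraitPopulationSpec,
    items_per_tree: dict[str, int],
    P: int,
    n_replications: int,
    settings: McmcSettings,
    seed: int = 0,
    priors: TraitPriors | None = None,
    max_reruns: int = 3,
) -> SimulationReport:
    """Generate-and-fit recovery study for the latent-trait model.

    Per replication: simulate with :func:`gen_trait_mpt`, fit with
    :func:`fit_trait` (slope parameters fitted as continuous predictors of
    the parameters carrying generating slopes), and record posterior means
    and 95% CIs of the probability-scale group means, probit SDs and
    standardized slopes. Replications with any R-hat >= 1.05 are re-run
    with doubled iterations up to ``max_reruns`` times, then excluded.
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    pred = (
        PredictorSpec(((tuple(spec.slopes), ("x",)),))
        if spec.slopes
        else PredictorSpec()
    )
    truth: dict[str, float] = {}
    for i, p in enumerate(model.parameters):
        truth[f"mean_{p}"] = float(ndtr(spec.mu_probit[i]))
        truth[f"sigma_{p}"] = float(spec.sigma_probit[i])
    for p, b in spec.slopes.items():
        truth[f"beta_{p}_x"] = float(b)

    records: list[dict] = []
    n_excluded = 0
    for rep in range(n_replications):
        rep_seed = int(rng.integers(2**31))
        data, _, covariates = gen_trait_mpt(
            P, items_per_tree, spec, model, seed=rep_seed
        )
        s = settings
        converged = False
        for attempt in range(max_reruns + 1):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = fit_trait(
                    model, data, covariates, pred, priors,
                    McmcSettings(
                        n_iter=s.n_iter * 2**attempt,
                        n_burnin=s.n_burnin * 2**attempt,
                        thin=s.thin,
                        n_chains=s.n_chains,
                        seed=rep_seed + attempt,
                        target_acceptance=s.target_acceptance,
                    ),
                )
            core = fit.convergence.table
            core = core.loc[[n for n in truth if n in core.index]]
            if core["rhat"].max() < 1.05:
                converged = True
                break
        if not converged:
            n_excluded += 1
            continue
        row: dict = {"replication": rep, "converged": converged}
        for name in truth:
            d = fit.draws.flat(name)
            row[f"{name}:mean"] = float(d.mean())
            row[f"{name}:lo"] = float(np.quantile(d, 0.025))
            row[f"{name}:hi"] = float(np.quantile(d, 0.975))
        records.append(row)

    rec = pd.DataFrame(records)
    rows = []
    for name, true_val in truth.items():
        pm = rec[f"{name}:mean"]
        lo = rec[f"{name}:lo"]
        hi = rec[f"{name}:hi"]
        row = {
            "quantity": name,
            "generating": true_val,
            "posterior_mean": float(pm.mean()),
            "ci_low": float(lo.mean()),
            "ci_high": float(hi.mean()),
            "abs_bias": float(np.mean(np.abs(pm - true_val))),
            "coverage_pct": float(100 * np.mean((lo <= true_val) & (true_val <= hi))),
        }
        if name.startswith("beta_"):
            row["zero_excluded_pct"] = float(100 * np.mean((lo > 0) | (hi < 0)))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("quantity")
    return SimulationReport(table, rec, len(rec), n_excluded)
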