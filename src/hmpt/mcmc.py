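"""Model-agnostic MCMC infrastructure.

A *kernel* bundles the update steps of one model: it knows how to draw an
initial state, how to perform one full sweep over all blocks (conjugate
Gibbs where available, adaptive random-walk Metropolis elsewhere), and how
to flatten a state into named scalars for storage. The engine here runs
multiple independent chains from deterministic sub-seeds, adapts proposal
scales only during burn-in (Robbins-Monro on the log scale, so the
post-burn-in chain is a valid Markov chain), thins, and provides
convergence diagnostics (split-chain R-hat, effective sample size) and run
extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "run_chains",
    "gelman_rubin",
    "extend_run",
    "summarize_draws",
    "adapt_step_size",
]

#: default quantiles reported by :func:`summarize_draws`
DEFAULT_PROBS = (0.025, 0.5, 0.975)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; defaults follow common hierarchical-MPT practice:
    20,000 iterations, 2,000 burn-in, keep every 5th draw, 3 chains."""

    n_iter: int = 20_000
    n_burnin: int = 2_000
    thin: int = 5
    n_chains: int = 3
    seed: int = 0
    target_acceptance: float = 0.35

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


def chain_rng(seed: int, chain: int) -> np.random.Generator:
    """Deterministic per-chain generator: SeedSequence(seed, spawn_key=(chain,))."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(chain,)))
    )


def adapt_step_size(iteration: int, c0: float = 1.0) -> float:
    """Robbins-Monro step c0 / ceil(i/50); vanishes, so adaptation is fair."""
    return c0 / np.ceil(iteration / 50.0)


@dataclass
class PosteriorDraws:
    """Retained posterior draws of all chains plus restart information.

    ``draws`` has shape (n_chains, n_retained, n_scalars); ``names`` maps
    each scalar column to a structured parameter name such as ``mu_D`` or
    ``theta_D[3]``.
    """

    draws: np.ndarray
    names: list[str]
    settings: McmcSettings
    final_states: list[dict] = field(default_factory=list)
    final_rngs: list[np.random.Generator] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, scalars)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("name registry does not match draw width")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one scalar, shape (chains, retained)."""
        if name not in self._index:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled, shape (chains * retained,)."""
        return self.get(name).reshape(-1)

    def matching(self, prefix: str) -> list[str]:
        return [n for n in self.names if n.startswith(prefix)]

    def to_dataframe(self) -> pd.DataFrame:
        c, n, d = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * n, d), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        df.insert(1, "iteration", np.tile(np.arange(n), c))
        return df

    def export(self, csv_path, meta_path=None) -> None:
        """Flat CSV of draws plus a JSON metadata sidecar."""
        self.to_dataframe().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "settings": asdict(self.settings),
                "names": self.names,
                "n_chains": self.n_chains,
                "n_retained": self.n_retained,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _init_state(kernel, rng: np.random.Generator) -> dict:
    last_err = None
    for _ in range(10):
        state = kernel.init(rng)
        logp = kernel.log_posterior(state) if hasattr(kernel, "log_posterior") else 0.0
        if np.isfinite(logp):
            return state
        last_err = logp
    raise RuntimeError(
        f"could not find a finite starting point after 10 draws (logp={last_err})"
    )


def run_chains(kernel, settings: McmcSettings) -> PosteriorDraws:
    """Run independent adaptive Metropolis-within-Gibbs chains.

    The kernel contract: ``init(rng) -> state``, ``sweep(state, rng,
    iteration, adapting)`` mutating the state in place (proposal scales live
    inside the state and may only change while ``adapting``), ``record(state)
    -> 1-D array`` aligned with ``kernel.param_names``, and optionally
    ``log_posterior(state)`` used to validate starting points.
    """
    names = list(kernel.param_names)
    keep = settings.n_retained
    draws = np.empty((settings.n_chains, keep, len(names)))
    final_states: list[dict] = []
    final_rngs: list[np.random.Generator] = []
    for c in range(settings.n_chains):
        rng = chain_rng(settings.seed, c)
        state = _init_state(kernel, rng)
        k = 0
        for it in range(1, settings.n_iter + 1):
            kernel.sweep(state, rng, it, adapting=it <= settings.n_burnin)
            if it > settings.n_burnin and (it - settings.n_burnin) % settings.thin == 0:
                if k < keep:
                    draws[c, k] = kernel.record(state)
                    k += 1
        final_states.append(state)
        final_rngs.append(rng)
    return PosteriorDraws(draws, names, settings, final_states, final_rngs)


def extend_run(draws: PosteriorDraws, kernel, extra_iter: int) -> PosteriorDraws:
    """Continue every chain from its stored final state and concatenate.

    Proposal scales stay frozen (no burn-in on extension); the thinning
    rate is inherited from the original settings.
    """
    if extra_iter < 0:
        raise ValueError("extra_iter must be >= 0")
    if extra_iter == 0:
        return draws
    if not draws.final_states:
        raise ValueError("draws carry no final states; cannot extend")
    s = draws.settings
    keep = extra_iter // s.thin
    new = np.empty((draws.n_chains, keep, len(draws.names)))
    for c in range(draws.n_chains):
        state = draws.final_states[c]
        rng = draws.final_rngs[c]
        k = 0
        for it in range(1, extra_iter + 1):
            kernel.sweep(state, rng, s.n_iter + it, adapting=False)
            if it % s.thin == 0 and k < keep:
                new[c, k] = kernel.record(state)
                k += 1
    return PosteriorDraws(
        np.concatenate([draws.draws, new], axis=1),
        draws.names,
        s,
        draws.final_states,
        draws.final_rngs,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter split-chain R-hat and effective sample size."""

    table: pd.DataFrame  # index = parameter, columns = rhat, ess, degenerate

    @property
    def max_rhat(self) -> float:
        ok = self.table.loc[~self.table["degenerate"], "rhat"]
        return float(ok.max()) if len(ok) else 1.0

    def converged(self, threshold: float = 1.05) -> bool:
        return self.max_rhat < threshold


def _split_chains(x: np.ndarray) -> np.ndarray:
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half:]], axis=0)


def _rhat_scalar(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for (chains, n) draws."""
    x = _split_chains(x)
    m, n = x.shape
    means = x.mean(axis=1)
    W = float(x.var(axis=1, ddof=1).mean())
    B = n * float(means.var(ddof=1))
    var_plus = (n - 1) / n * W + B / n
    if W <= 0:
        return 1.0
    return float(np.sqrt(var_plus / W))


def _ess_scalar(x: np.ndarray) -> float:
    """ESS via chain-averaged autocorrelations, truncated at the first
    negative pair (Geyer's initial positive sequence)."""
    m, n = x.shape
    var_plus = 0.0
    W = float(x.var(axis=1, ddof=1).mean())
    means = x.mean(axis=1)
    B = n * float(means.var(ddof=1)) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + (B / n if m > 1 else 0.0)
    if var_plus <= 0:
        return float(m * n)
    # chain-averaged autocovariances via FFT
    acov = np.zeros(n)
    for c in range(m):
        d = x[c] - x[c].mean()
        f = np.fft.rfft(d, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    rho = 1.0 - (W - acov) / var_plus
    rho[0] = 1.0
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / tau)


def gelman_rubin(draws: PosteriorDraws | np.ndarray, names=None) -> ConvergenceReport:
    """Split-chain R-hat and ESS for every stored scalar.

    Accepts :class:`PosteriorDraws` or a raw (chains, n, scalars) array.
    Zero-variance parameters are reported with R-hat 1 and flagged
    degenerate.
    """
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.draws, draws.names
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if names is None:
            names = [f"p{i}" for i in range(arr.shape[2])]
    if arr.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if arr.shape[1] < 10:
        raise ValueError("R-hat needs at least 10 retained iterations")
    rows = []
    for j, name in enumerate(names):
        x = arr[:, :, j]
        degenerate = bool(np.allclose(x.var(axis=1), 0.0))
        if degenerate:
            rows.append({"parameter": name, "rhat": 1.0, "ess": float("nan"),
                         "degenerate": True})
        else:
            rows.append(
                {
                    "parameter": name,
                    "rhat": _rhat_scalar(x),
                    "ess": _ess_scalar(x),
                    "degenerate": False,
                }
            )
    return ConvergenceReport(pd.DataFrame(rows).set_index("parameter"))


def summarize_draws(
    draws: PosteriorDraws, probs=DEFAULT_PROBS, names=None
) -> pd.DataFrame:
    """Posterior summary table: mean, SD, quantiles, R-hat, ESS."""
    sel = names if names is not None else draws.names
    conv = gelman_rubin(draws)
    rows = []
    for name in sel:
        x = draws.flat(name)
        row = {
            "parameter": name,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
        }
        for p in probs:
            row[f"q{100 * p:g}%"] = float(np.quantile(x, p))
        row["rhat"] = float(conv.table.loc[name, "rhat"])
        row["ess"] = float(conv.table.loc[name, "ess"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
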