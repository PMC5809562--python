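"""Product-multinomial likelihood of an MPT model.

Branch and category probabilities are polynomial in the parameters; for
speed, a model is compiled once into exponent matrices so that category
probabilities for a whole participant x parameter matrix evaluate as two
matrix products (log-space for the branch polynomials, then a branch-to-
category aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eqn import Branch, MptModel

__all__ = [
    "FrequencyTable",
    "CompiledModel",
    "compile_model",
    "branch_probability",
    "category_probabilities",
    "log_likelihood",
    "expected_frequencies",
    "read_frequencies_csv",
]

#: distance kept from the {0,1} boundary when clipping theta before logs
THETA_EPS = 1e-9


@dataclass
class FrequencyTable:
    """Participant x category response counts.

    ``counts[p, k]`` is the frequency of category ``category_labels[k]`` for
    participant ``row_ids[p]``; ``tree_of_category`` assigns each category
    to its multinomial tree. Columns are matched to a model by label, never
    by position.
    """

    counts: np.ndarray
    category_labels: list[str]
    tree_of_category: dict[str, str]
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D participant x category matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not valid frequencies")
        if self.counts.shape[1] != len(self.category_labels):
            raise ValueError("counts width does not match category labels")
        if self.row_ids is None:
            self.row_ids = [str(i) for i in range(self.counts.shape[0])]

    @property
    def n_participants(self) -> int:
        return self.counts.shape[0]

    @property
    def trees(self) -> list[str]:
        seen: list[str] = []
        for c in self.category_labels:
            t = self.tree_of_category[c]
            if t not in seen:
                seen.append(t)
        return seen

    def aligned_to(self, model: MptModel) -> "FrequencyTable":
        """Reorder columns to the model's category order (match by label)."""
        want = list(model.category_labels)
        have = set(self.category_labels)
        missing = [c for c in want if c not in have]
        extra = [c for c in self.category_labels if c not in set(want)]
        if missing or extra:
            raise ValueError(
                f"category labels do not match the model; missing={missing}, "
                f"unmatched={extra}"
            )
        idx = [self.category_labels.index(c) for c in want]
        return FrequencyTable(
            counts=self.counts[:, idx],
            category_labels=want,
            tree_of_category=dict(model.categories),
            row_ids=list(self.row_ids),
        )

    def tree_totals(self) -> np.ndarray:
        """P x T per-tree response totals (tree order as in :attr:`trees`)."""
        trees = self.trees
        out = np.zeros((self.n_participants, len(trees)), dtype=float)
        for j, c in enumerate(self.category_labels):
            out[:, trees.index(self.tree_of_category[c])] += self.counts[:, j]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_ids, columns=self.category_labels
        )


def read_frequencies_csv(path_or_buffer, model: MptModel) -> FrequencyTable:
    """Read a frequency CSV (header = category labels, one row/participant).

    A non-numeric first column is auto-detected as participant identifiers.
    """
    df = pd.read_csv(path_or_buffer)
    first = df.columns[0]
    row_ids = None
    if first not in set(model.category_labels) and not np.issubdtype(
        df[first].dtype, np.number
    ):
        row_ids = [str(v) for v in df[first]]
        df = df.drop(columns=[first])
    table = FrequencyTable(
        counts=df.to_numpy(),
        category_labels=[str(c) for c in df.columns],
        tree_of_category={},
        row_ids=row_ids,
    )
    table.tree_of_category = dict(model.categories)
    return table.aligned_to(model)


@dataclass(frozen=True)
class CompiledModel:
    """Array form of an MPT model for vectorized evaluation."""

    model: MptModel
    const: np.ndarray        # (B,) branch constants c_ik
    expo_a: np.ndarray       # (B, S) theta exponents
    expo_b: np.ndarray       # (B, S) (1-theta) exponents
    branch_to_cat: np.ndarray  # (B, K) 0/1 aggregation matrix
    cat_tree_index: np.ndarray  # (K,) index into model.trees per category

    @property
    def n_categories(self) -> int:
        return self.branch_to_cat.shape[1]


def compile_model(model: MptModel) -> CompiledModel:
    S = model.n_parameters
    B = len(model.branches)
    K = len(model.categories)
    pidx = {name: i for i, name in enumerate(model.parameters)}
    cidx = {name: i for i, name in enumerate(model.category_labels)}
    const = np.empty(B)
    ea = np.zeros((B, S))
    eb = np.zeros((B, S))
    agg = np.zeros((B, K))
    for i, b in enumerate(model.branches):
        const[i] = b.constant_c
        for name, k in b.exponents_a.items():
            ea[i, pidx[name]] = k
        for name, k in b.exponents_b.items():
            eb[i, pidx[name]] = k
        agg[i, cidx[b.category_label]] = 1.0
    tree_index = np.array(
        [model.trees.index(t) for _, t in model.categories], dtype=int
    )
    return CompiledModel(model, const, ea, eb, agg, tree_index)


def _clip(theta: np.ndarray) -> np.ndarray:
    return np.clip(theta, THETA_EPS, 1.0 - THETA_EPS)


def branch_probability(theta_row, branch: Branch, model: MptModel) -> float:
    """Probability of a single branch at one parameter vector."""
    theta_row = np.asarray(theta_row, dtype=float)
    unknown = (set(branch.exponents_a) | set(branch.exponents_b)) - set(
        model.parameters
    )
    if unknown:
        raise KeyError(f"branch references unknown parameters: {sorted(unknown)}")
    theta = dict(zip(model.parameters, _clip(theta_row)))
    return branch.probability(theta)


def category_probabilities(theta, compiled: CompiledModel | MptModel) -> np.ndarray:
    """Category probabilities for one theta row or a P x S matrix.

    Returns shape (K,) for a 1-D input, (P, K) for 2-D.
    """
    if isinstance(compiled, MptModel):
        compiled = compile_model(compiled)
    theta = np.asarray(theta, dtype=float)
    one_row = theta.ndim == 1
    probs = _cat_probs_matrix(theta, compiled)
    return probs[0] if one_row else probs


def _cat_probs_matrix(theta: np.ndarray, compiled: CompiledModel) -> np.ndarray:
    th = _clip(np.atleast_2d(theta))
    log_branch = (
        np.log(th) @ compiled.expo_a.T
        + np.log1p(-th) @ compiled.expo_b.T
        + np.log(compiled.const)
    )
    return np.exp(log_branch) @ compiled.branch_to_cat


def log_likelihood(
    theta,
    data: FrequencyTable,
    model: MptModel | CompiledModel,
    per_participant: bool = False,
) -> float | np.ndarray:
    """Product-multinomial log-likelihood (multinomial coefficient omitted).

    ``theta`` is a P x S matrix (or a single row for P=1); ``data`` must be
    aligned to the model's categories by label.
    """
    compiled = compile_model(model) if isinstance(model, MptModel) else model
    data = data.aligned_to(compiled.model)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] != data.n_participants:
        raise ValueError(
            f"theta has {theta.shape[0]} rows but data has "
            f"{data.n_participants} participants"
        )
    probs = _cat_probs_matrix(theta, compiled)
    ll = np.sum(data.counts * np.log(np.maximum(probs, 1e-300)), axis=1)
    return ll if per_participant else float(np.sum(ll))


def expected_frequencies(
    theta, items_per_tree: dict[str, int | float], model: MptModel | CompiledModel
) -> np.ndarray:
    """Expected P x K frequency matrix: n_t * P(C_k | theta_p)."""
    compiled = compile_model(model) if isinstance(model, MptModel) else model
    m = compiled.model
    missing = [t for t in m.trees if t not in items_per_tree]
    if missing:
        raise KeyError(f"items_per_tree missing trees: {missing}")
    n_t = np.array([float(items_per_tree[t]) for t in m.trees])
    if np.any(n_t <= 0):
        raise ValueError("items_per_tree must be positive")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    probs = _cat_probs_matrix(theta, compiled)
    return probs * n_t[compiled.cat_tree_index]
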