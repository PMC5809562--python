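"""Tests of participant homogeneity, run before hierarchical modeling.

If all participants share one parameter vector, individual frequency rows
are i.i.d. multinomial within each tree. Two tests of that null are
provided: an asymptotic chi-square test (items assumed homogeneous) and an
item-wise permutation test that remains valid when items are heterogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import FrequencyTable

__all__ = [
    "LongData",
    "HomogeneityResult",
    "chisq_participant_heterogeneity",
    "permutation_participant_heterogeneity",
    "frequency_summary",
    "read_long_csv",
]


@dataclass
class LongData:
    """Long-format responses: one record per (participant, item, response).

    ``tree_map`` assigns each response-category label to exactly one tree.
    """

    participants: np.ndarray
    items: np.ndarray
    responses: np.ndarray
    tree_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.participants = np.asarray(self.participants)
        self.items = np.asarray(self.items)
        self.responses = np.asarray(self.responses)
        n = len(self.participants)
        if not (len(self.items) == n == len(self.responses)):
            raise ValueError("participant/item/response columns differ in length")
        seen: dict[str, str] = {}
        for tree, cats in self.tree_map.items():
            for c in cats:
                if c in seen:
                    raise ValueError(
                        f"category {c!r} assigned to trees {seen[c]!r} and {tree!r}"
                    )
                seen[c] = tree
        unknown = set(map(str, self.responses)) - set(seen)
        if unknown:
            raise ValueError(f"responses not covered by tree_map: {sorted(unknown)}")

    def to_frequency_table(self) -> FrequencyTable:
        labels = [c for cats in self.tree_map.values() for c in cats]
        tree_of = {c: t for t, cats in self.tree_map.items() for c in cats}
        pids = list(dict.fromkeys(map(str, self.participants)))
        counts = np.zeros((len(pids), len(labels)), dtype=int)
        pi = {p: i for i, p in enumerate(pids)}
        ci = {c: j for j, c in enumerate(labels)}
        for p, r in zip(map(str, self.participants), map(str, self.responses)):
            counts[pi[p], ci[r]] += 1
        return FrequencyTable(counts, labels, tree_of, pids)


def read_long_csv(path_or_buffer, tree_map: dict[str, list[str]]) -> LongData:
    """Read a 3-column long-format CSV (participant, item, response)."""
    df = pd.read_csv(path_or_buffer, header=None)
    if df.shape[1] < 3:
        raise ValueError("long format needs 3 columns: participant, item, response")
    # tolerate a header row: drop it if the third field is not a known category
    known = {c for cats in tree_map.values() for c in cats}
    if str(df.iloc[0, 2]) not in known:
        df = df.iloc[1:]
    return LongData(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].to_numpy(),
        df.iloc[:, 2].astype(str).to_numpy(),
        tree_map,
    )


@dataclass(frozen=True)
class HomogeneityResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    n_permutations: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.method == "chisq":
            return (
                f"chi^2({self.df}) = {self.statistic:.1f}, p = {self.p_value:.3g}"
            )
        return (
            f"permutation test ({self.n_permutations} permutations): "
            f"statistic = {self.statistic:.1f}, p = {self.p_value:.4f}"
        )


def _chisq_statistic(counts: np.ndarray, tree_index: np.ndarray) -> tuple[float, int]:
    """Participant-homogeneity chi-square summed over trees.

    For each tree, pooled category proportions define the expected counts
    n_pt * p_hat_k per participant; the statistic is the Pearson sum over
    participants and categories, with df = (P-1) * sum_t (K_t - 1).
    """
    P = counts.shape[0]
    stat = 0.0
    df = 0
    for t in np.unique(tree_index):
        sub = counts[:, tree_index == t].astype(float)
        col_tot = sub.sum(axis=0)
        if np.any(col_tot == 0):
            warnings.warn(
                "category with pooled count 0 dropped from chi-square test",
                stacklevel=3,
            )
            sub = sub[:, col_tot > 0]
            col_tot = col_tot[col_tot > 0]
        row_tot = sub.sum(axis=1)
        if np.any(row_tot == 0):
            raise ValueError("every participant needs responses in every tree")
        p_hat = col_tot / col_tot.sum()
        expected = np.outer(row_tot, p_hat)
        stat += float(np.sum((sub - expected) ** 2 / expected))
        df += (P - 1) * (sub.shape[1] - 1)
    return stat, df


def chisq_participant_heterogeneity(data: FrequencyTable) -> HomogeneityResult:
    """Asymptotic chi-square test of identical response distributions.

    Assumes homogeneous items; under the null of exchangeable participants
    the statistic is chi-square with (P-1) * sum_t (K_t - 1) degrees of
    freedom.
    """
    if data.n_participants < 2:
        raise ValueError("need at least 2 participants")
    trees = data.trees
    tree_index = np.array(
        [trees.index(data.tree_of_category[c]) for c in data.category_labels]
    )
    stat, df = _chisq_statistic(data.counts, tree_index)
    p = float(stats.chi2.sf(stat, df))
    return HomogeneityResult(stat, df, p, "chisq")


def permutation_participant_heterogeneity(
    data: LongData, n_perm: int = 10_000, seed: int = 0
) -> HomogeneityResult:
    """Permutation test of participant homogeneity, robust to item effects.

    The observed statistic is the chi-square statistic computed from the
    participant x category table. The null distribution is generated by
    independently permuting, within each item, the responses across the
    participants who responded to it — preserving item margins while
    breaking participant identity. p uses the add-one estimator
    (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pair_index = {}
    for p, i in zip(map(str, data.participants), map(str, data.items)):
        if (p, i) in pair_index:
            raise ValueError(f"duplicate (participant, item) pair: {(p, i)}")
        pair_index[(p, i)] = True

    labels = [c for cats in data.tree_map.values() for c in cats]
    trees = list(data.tree_map)
    tree_index = np.array(
        [trees.index(t) for t, cats in data.tree_map.items() for _ in cats]
    )
    pids = list(dict.fromkeys(map(str, data.participants)))
    pi = {p: i for i, p in enumerate(pids)}
    ci = {c: j for j, c in enumerate(labels)}
    p_codes = np.array([pi[p] for p in map(str, data.participants)])
    r_codes = np.array([ci[r] for r in map(str, data.responses)])
    items = np.asarray(list(map(str, data.items)))

    def table(resp_codes: np.ndarray) -> np.ndarray:
        counts = np.zeros((len(pids), len(labels)), dtype=np.int64)
        np.add.at(counts, (p_codes, resp_codes), 1)
        return counts

    observed, _ = _chisq_statistic(table(r_codes), tree_index)
    rng = np.random.default_rng(seed)
    item_groups = [np.flatnonzero(items == it) for it in np.unique(items)]
    n_ge = 0
    resp = r_codes.copy()
    for _ in range(n_perm):
        for idx in item_groups:
            resp[idx] = r_codes[idx][rng.permutation(len(idx))]
        stat, _ = _chisq_statistic(table(resp), tree_index)
        if stat >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return HomogeneityResult(observed, None, p, "permutation", n_perm)


def frequency_summary(data: FrequencyTable, relative: bool = False) -> pd.DataFrame:
    """Per-category distribution of individual frequencies (boxplot data).

    Returns quartiles, whiskers (1.5 IQR rule, clamped to the data range)
    and the mean per category; with ``relative=True`` counts are divided by
    the participant's per-tree total, so means per tree sum to 1.
    """
    counts = data.counts.astype(float)
    if relative:
        trees = data.trees
        totals = data.tree_totals()
        for j, c in enumerate(data.category_labels):
            counts[:, j] = counts[:, j] / totals[:, trees.index(data.tree_of_category[c])]
    rows = []
    for j, c in enumerate(data.category_labels):
        col = counts[:, j]
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        iqr = q3 - q1
        lo = float(col[col >= q1 - 1.5 * iqr].min())
        hi = float(col[col <= q3 + 1.5 * iqr].max())
        rows.append(
            {
                "category": c,
                "tree": data.tree_of_category[c],
                "mean": float(col.mean()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "whisker_low": lo,
                "whisker_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("category")
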