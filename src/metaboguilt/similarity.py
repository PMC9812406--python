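"""Mutant similarity from fold-change profiles.

Per timepoint: pairwise-complete Pearson correlations between mutant
fold-change vectors, Manhattan distances between rows of that correlation
matrix, Ward agglomeration on the resulting dissimilarities, and
correlation against an external pairwise score table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterTree",
    "correlation_matrix",
    "manhattan_distance_matrix",
    "ward_cluster",
    "compare_to_external_scores",
]


def correlation_matrix(
    profiles: pd.DataFrame, timepoint_min: float, min_shared: int = 3
) -> pd.DataFrame:
    """Mutant x mutant Pearson correlations of fold-change profiles.

    Correlations are computed over the metabolites shared (non-missing) by
    each pair of mutants at the given timepoint.  Mutants whose profile has
    zero variance are excluded with a warning.
    """
    sub = profiles[profiles["timepoint_min"] == timepoint_min]
    if sub.empty:
        raise ValueError(f"no profiles at timepoint {timepoint_min}")
    wide = sub.pivot(index="metabolite_id", columns="mutant", values="mean_log2_fc")

    degenerate = [m for m in wide.columns if wide[m].dropna().nunique() <= 1]
    if degenerate:
        warnings.warn(
            f"excluding zero-variance profiles at t={timepoint_min}: {degenerate}",
            stacklevel=2,
        )
        wide = wide.drop(columns=degenerate)

    corr = wide.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def manhattan_distance_matrix(
    corr: pd.DataFrame, include_self: bool = True
) -> pd.DataFrame:
    """Manhattan distances between rows of a correlation matrix.

    ``D[a, b] = sum_k |r[a, k] - r[b, k]|`` over every mutant k, including
    by default the diagonal and the pair's mutual entries;
    ``include_self=False`` drops columns a and b from each pair's sum.
    """
    r = corr.to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("correlation matrix contains missing values")
    diff = np.abs(r[:, None, :] - r[None, :, :])
    d = diff.sum(axis=2)
    if not include_self:
        n = r.shape[0]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        d = d - diff[i, j, i] - diff[i, j, j]
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=corr.index, columns=corr.columns)


@dataclass
class ClusterTree:
    """Agglomeration history: leaves, merges (ids, height, size), leaf order."""

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]  # ids of merged nodes; leaves are 0..n-1

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def linkage(self) -> np.ndarray:
        """The merge history as a scipy-style (n-1) x 4 linkage array."""
        return np.array(self.merges, dtype=float)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf ordering implied by the merge history."""

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b, _, _ = self.merges[node - self.n_leaves]
            return walk(int(a)) + walk(int(b))

        root = self.n_leaves + len(self.merges) - 1
        return [self.leaves[i] for i in walk(root)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Leaf partition obtained by undoing the last ``n_clusters - 1`` merges."""
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        keep = len(self.merges) - (n_clusters - 1)
        for step, (a, b, _, _) in enumerate(self.merges[:keep]):
            node = self.n_leaves + step
            parent[find(int(a))] = node
            parent[find(int(b))] = node
        roots = {}
        labels = {}
        for i, name in enumerate(self.leaves):
            r = find(i)
            labels[name] = roots.setdefault(r, len(roots))
        return labels

    def to_newick(self) -> str:
        """Newick rendering with merge heights as node heights."""
        heights = [0.0] * self.n_leaves + [h for _, _, h, _ in self.merges]

        def render(node: int, parent_h: float) -> str:
            length = parent_h - heights[node]
            if node < self.n_leaves:
                return f"{self.leaves[node]}:{length:g}"
            a, b, h, _ = self.merges[node - self.n_leaves]
            inner = f"({render(int(a), h)},{render(int(b), h)})"
            return f"{inner}:{length:g}" if parent_h != h else inner

        root = self.n_leaves + len(self.merges) - 1
        return render(root, heights[root]) + ";"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "leaves": self.leaves,
                    "merges": [
                        {"a": int(a), "b": int(b), "height": h, "size": int(s)}
                        for a, b, h, s in self.merges
                    ],
                },
                fh,
                indent=1,
            )


def ward_cluster(dist: pd.DataFrame) -> ClusterTree:
    """Agglomerate with the Lance-Williams Ward update on the given matrix.

    The update is applied to the supplied dissimilarities as-is (no
    squaring), which is the literal reading of "Ward's method applied to
    Manhattan distances"; on a non-Euclidean dissimilarity Ward is not a
    variance decomposition, but the merge sequence is still well defined.
    Ties are broken by the lexicographically smallest (i, j) node-id pair.
    """
    d = dist.to_numpy(dtype=float).copy()
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    leaves = [str(x) for x in dist.index]
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> cluster size
    # current dissimilarity between active nodes, keyed by sorted id pair
    cur: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), height = min(cur.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = active.pop(a), active.pop(b)
        size = na + nb
        new = {}
        for k, nk in active.items():
            dak = cur.pop((min(a, k), max(a, k)))
            dbk = cur.pop((min(b, k), max(b, k)))
            dab = height
            new[(k, next_id)] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * dab
            ) / (size + nk)
        cur.pop((a, b))
        cur.update(new)
        merges.append((a, b, float(height), size))
        active[next_id] = size
        next_id += 1
    return ClusterTree(leaves=leaves, merges=merges)


def compare_to_external_scores(
    dist: pd.DataFrame, pair_scores: pd.DataFrame
) -> dict:
    """Correlate pairwise distances with an external (mutant, mutant, score) table.

    Returns Pearson and Spearman statistics over the overlapping unordered
    pairs (>= 3 required).
    """
    cols = list(pair_scores.columns[:3])
    seen = set()
    xs, ys = [], []
    index = {m: i for i, m in enumerate(dist.index)}
    for m1, m2, score in pair_scores[cols].itertuples(index=False):
        if m1 not in index or m2 not in index or m1 == m2:
            continue
        key = tuple(sorted((m1, m2)))
        if key in seen:
            continue
        seen.add(key)
        xs.append(dist.iat[index[m1], index[m2]])
        ys.append(float(score))
    if len(xs) < 3:
        raise ValueError("need at least 3 overlapping mutant pairs")
    pearson = stats.pearsonr(xs, ys)
    spearman = stats.spearmanr(xs, ys)
    return {
        "n_pairs": len(xs),
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
    }
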