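import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metaboguilt import (
    compare_to_external_scores,
    correlation_matrix,
    log2_fold_change_profiles,
    manhattan_distance_matrix,
    ward_cluster,
)


def _profiles_from_vectors(vectors: dict[str, list[float]], timepoint=30.0):
    rows = []
    for mutant, values in vectors.items():
        for j, v in enumerate(values):
            rows.append(
                {
                    "mutant": mutant,
                    "timepoint_min": timepoint,
                    "metabolite_id": f"m{j}",
                    "mean_log2_fc": v,
                    "p_value": 0.5,
                    "n_mutant_reps": 4,
                    "n_wt_reps": 4,
                }
            )
    return pd.DataFrame(rows)


def _square(values, names):
    return pd.DataFrame(np.asarray(values, dtype=float), index=names, columns=names)


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self):
        p = _profiles_from_vectors({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        corr = correlation_matrix(p, 30.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        p = _profiles_from_vectors({"a": [1, 2, 3], "b": [-1, -2, -3]})
        corr = correlation_matrix(p, 30.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        p = _profiles_from_vectors({"a": list(x), "b": list(y)})
        corr = correlation_matrix(p, 30.0)
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        other = rng.normal(size=8)
        p1 = _profiles_from_vectors({"a": list(base), "b": list(other)})
        p2 = _profiles_from_vectors(
            {"a": list(2.7 * base + 3.1), "b": list(other)}
        )
        c1 = correlation_matrix(p1, 30.0)
        c2 = correlation_matrix(p2, 30.0)
        assert c1.loc["a", "b"] == pytest.approx(c2.loc["a", "b"], abs=1e-12)

    def test_pairwise_complete_over_shared_metabolites(self):
        p = _profiles_from_vectors(
            {"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10], "c": [5, 4, 3, 2, 1]}
        )
        p.loc[(p["mutant"] == "b") & (p["metabolite_id"] == "m4"), "mean_log2_fc"] = (
            np.nan
        )
        corr = correlation_matrix(p, 30.0)
        # a-b computed over m0..m3 only, still perfectly linear
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_profile_excluded_with_warning(self):
        p = _profiles_from_vectors(
            {"a": [1, 2, 3], "b": [0, 0, 0], "c": [3, 1, 2]}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(p, 30.0)
        assert list(corr.index) == ["a", "c"]

    def test_empty_timepoint_rejected(self):
        p = _profiles_from_vectors({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            correlation_matrix(p, 60.0)


class TestManhattanDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        corr = _square([[1, 0.5], [0.5, 1]], ["a", "b"])
        corr.loc["a"] = corr.loc["b"] = [0.7, 0.7]
        d = manhattan_distance_matrix(corr)
        assert d.loc["a", "b"] == 0.0

    def test_hand_summed_example(self):
        # rows (1, 0, 0.5) and (0, 1, 0.5): |1-0| + |0-1| + 0 = 2
        corr = _square(
            [[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]], ["a", "b", "c"]
        )
        d = manhattan_distance_matrix(corr)
        assert d.loc["a", "b"] == pytest.approx(2.0, abs=1e-12)

    def test_naive_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(3, 20)
            r = np.clip(rng.normal(0, 0.5, (n, n)), -1, 1)
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            names = [f"g{i}" for i in range(n)]
            d = manhattan_distance_matrix(_square(r, names)).to_numpy()
            for i in range(n):
                for j in range(n):
                    expected = sum(abs(r[i, k] - r[j, k]) for k in range(n))
                    if i == j:
                        expected = 0.0
                    assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            r = rng.uniform(-1, 1, (10, 10))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            d = manhattan_distance_matrix(
                _square(r, [f"g{i}" for i in range(10)])
            ).to_numpy()
            for i, j, k in itertools.permutations(range(10), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_exclude_self_option(self):
        corr = _square(
            [[1.0, 0.2, 0.5], [0.2, 1.0, 0.9], [0.5, 0.9, 1.0]], ["a", "b", "c"]
        )
        d = manhattan_distance_matrix(corr, include_self=False)
        # only the third column survives for the (a, b) pair
        assert d.loc["a", "b"] == pytest.approx(abs(0.5 - 0.9), abs=1e-12)

    def test_missing_correlations_rejected(self):
        corr = _square([[1.0, np.nan], [np.nan, 1.0]], ["a", "b"])
        with pytest.raises(ValueError):
            manhattan_distance_matrix(corr)


def lance_williams_ward_oracle(d: np.ndarray):
    """Independent step-by-step Ward agglomeration for test comparison."""
    n = d.shape[0]
    dd = {
        (i, j): d[i, j] for i in range(n) for j in range(n) if i < j
    }
    sizes = {i: 1 for i in range(n)}
    merges = []
    nxt = n
    while len(sizes) > 1:
        best = min(dd, key=lambda p: (dd[p], p))
        h = dd[best]
        a, b = best
        na, nb = sizes.pop(a), sizes.pop(b)
        others = list(sizes)
        for k in others:
            dak = dd.pop(tuple(sorted((a, k))))
            dbk = dd.pop(tuple(sorted((b, k))))
            nk = sizes[k]
            dd[(k, nxt)] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * h
            ) / (na + nb + nk)
        del dd[best]
        merges.append((a, b, h, na + nb))
        sizes[nxt] = na + nb
        nxt += 1
    return merges


class TestWardCluster:
    def test_two_leaves_single_merge(self):
        d = _square([[0, 3.5], [3.5, 0]], ["a", "b"])
        tree = ward_cluster(d)
        assert tree.merges == [(0, 1, 3.5, 2)]

    def test_unique_minimum_merges_first(self):
        d = _square([[0, 1, 10], [1, 0, 10], [10, 10, 0]], ["a", "b", "c"])
        tree = ward_cluster(d)
        assert tree.merges[0][:2] == (0, 1)

    def test_matches_hand_lance_williams_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            m = rng.uniform(1, 10, (6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = ward_cluster(_square(m, list("abcdef")))
            expected = lance_williams_ward_oracle(m)
            assert len(tree.merges) == len(expected) == 5
            for got, exp in zip(tree.merges, expected):
                assert got[0] == exp[0] and got[1] == exp[1]
                assert got[2] == pytest.approx(exp[2], rel=1e-12)
                assert got[3] == exp[3]

    def test_heights_nondecreasing_on_metric_input(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=2)
        tree = ward_cluster(_square(d, [f"p{i}" for i in range(8)]))
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(heights, heights[1:]))

    def test_partition_invariant_under_leaf_order(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(1, 10, (7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        names = [f"g{i}" for i in range(7)]
        tree1 = ward_cluster(_square(m, names))
        perm = rng.permutation(7)
        m2 = m[np.ix_(perm, perm)]
        names2 = [names[i] for i in perm]
        tree2 = ward_cluster(_square(m2, names2))
        for k in (2, 3, 4):
            p1 = tree1.cut(k)
            p2 = tree2.cut(k)
            parts1 = {
                frozenset(n for n, c in p1.items() if c == cl)
                for cl in set(p1.values())
            }
            parts2 = {
                frozenset(n for n, c in p2.items() if c == cl)
                for cl in set(p2.values())
            }
            assert parts1 == parts2

    def test_newick_roundtrip_leaf_set(self):
        import dendropy

        rng = np.random.default_rng(6)
        m = rng.uniform(1, 5, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        names = ["aa", "bb", "cc", "dd", "ee"]
        tree = ward_cluster(_square(m, names))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(names)

    def test_asymmetric_input_rejected(self):
        d = _square([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], list("abc"))
        with pytest.raises(ValueError):
            ward_cluster(d)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(_square([[0.0]], ["a"]))


class TestCompareToExternalScores:
    def _dist(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 4, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return _square(m, [f"g{i}" for i in range(n)])

    def _pairs(self, dist, transform=lambda v: v):
        rows = []
        for i, a in enumerate(dist.index):
            for b in dist.index[i + 1 :]:
                rows.append((a, b, transform(dist.loc[a, b])))
        return pd.DataFrame(rows, columns=["m1", "m2", "score"])

    def test_self_scores_give_perfect_correlation(self):
        dist = self._dist()
        result = compare_to_external_scores(dist, self._pairs(dist))
        assert result["pearson_r"] == pytest.approx(1.0, abs=1e-12)

    def test_negated_scores_give_minus_one(self):
        dist = self._dist(1)
        result = compare_to_external_scores(dist, self._pairs(dist, lambda v: -v))
        assert result["pearson_r"] == pytest.approx(-1.0, abs=1e-12)

    def test_spearman_equals_rank_then_pearson(self):
        dist = self._dist(2, n=7)
        rng = np.random.default_rng(7)
        pairs = self._pairs(dist, lambda v: float(rng.normal()))
        subset = pairs.sample(20, random_state=0)
        result = compare_to_external_scores(dist, subset)
        xs = [dist.loc[a, b] for a, b, _ in subset.itertuples(index=False)]
        ys = subset["score"].tolist()
        expected = stats.pearsonr(stats.rankdata(xs), stats.rankdata(ys)).statistic
        assert result["spearman_rho"] == pytest.approx(expected, abs=1e-12)

    def test_no_overlap_rejected(self):
        dist = self._dist()
        pairs = pd.DataFrame(
            [("x1", "x2", 1.0), ("x3", "x4", 2.0), ("x5", "x6", 3.0)],
            columns=["m1", "m2", "score"],
        )
        with pytest.raises(ValueError):
            compare_to_external_scores(dist, pairs)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_manhattan_matches_cityblock(seed):
    from scipy.spatial.distance import cdist

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    r = rng.uniform(-1, 1, (n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    d = manhattan_distance_matrix(_square(r, [f"g{i}" for i in range(n)]))
    expected = cdist(r, r, metric="cityblock")
    assert np.allclose(d.to_numpy(), expected, atol=1e-12)
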