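"""Spearman statistics, Bonferroni adjustment, MST construction, layout."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicstack import (
    bonferroni,
    build_mst,
    layout_network,
    spearman_matrix,
)
from omicstack.network import FeatureNode
from omicstack.errors import NetworkError, ValidationError


def _nodes(k, modality="m"):
    return [FeatureNode(modality, f"f{i}", 0.0) for i in range(k)]


def _net_from_rho(absrho: np.ndarray):
    k = absrho.shape[0]
    rho = pd.DataFrame(absrho, index=[f"f{i}" for i in range(k)],
                       columns=[f"f{i}" for i in range(k)])
    p = pd.DataFrame(np.full((k, k), 0.01), index=rho.index,
                     columns=rho.columns)
    return build_mst(_nodes(k), rho, p)


class TestSpearmanMatrix:
    def test_identical_columns_reach_the_minimum_attainable_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=6)})
        rho, p = spearman_matrix(df)
        assert rho.loc["a", "b"] == 1.0
        # exactly two of 720 pairings achieve |rho| = 1
        assert p.loc["a", "b"] == pytest.approx(2 / math.factorial(6))

    def test_negated_column_gives_minus_one(self):
        x = np.arange(8.0)
        rho, _ = spearman_matrix(pd.DataFrame({"a": x, "b": -x}))
        assert rho.loc["a", "b"] == -1.0

    def test_small_n_matches_exhaustive_permutation_oracle(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        _, p = spearman_matrix(df)
        for a, b in itertools.combinations("abc", 2):
            ra = stats.rankdata(df[a])
            rb = stats.rankdata(df[b])
            obs = abs(stats.pearsonr(ra, rb).statistic)
            count = sum(
                abs(stats.pearsonr(ra, np.array(perm)).statistic) >= obs - 1e-12
                for perm in itertools.permutations(rb)
            )
            assert p.loc[a, b] == pytest.approx(count / 720)

    def test_large_n_uses_t_approximation(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(40, 4)))
        rho, p = spearman_matrix(df)
        ref = stats.spearmanr(df.to_numpy())
        np.testing.assert_allclose(rho.to_numpy(), ref.statistic, atol=1e-12)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(p.to_numpy()[off], ref.pvalue[off],
                                   atol=1e-12)

    def test_constant_column_pairs_are_degenerate(self):
        df = pd.DataFrame({"a": np.arange(12.0), "b": np.ones(12),
                           "c": np.arange(12.0) ** 2})
        rho, p = spearman_matrix(df)
        assert rho.loc["a", "b"] == 0.0 and p.loc["a", "b"] == 1.0
        assert rho.loc["a", "c"] == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(15, 3)))
        rho1, p1 = spearman_matrix(df)
        perm = rng.permutation(15)
        rho2, p2 = spearman_matrix(df.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy())
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy())


class TestBonferroni:
    @pytest.mark.parametrize("p,n,expected", [
        (0.004, 226, 0.904),
        (0.2, 10, 1.0),
        (0.05, 1, 0.05),
    ])
    def test_formula(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(min_value=0, max_value=1),
           n=st.integers(min_value=1, max_value=10**6))
    def test_monotone_and_idempotent_at_the_cap(self, p, n):
        adj = bonferroni(p, n)
        assert 0.0 <= adj <= 1.0
        assert adj >= bonferroni(p, max(1, n - 1)) - 1e-15
        assert bonferroni(adj, 1) == adj


class TestMST:
    def test_three_node_tree_keeps_the_two_short_edges(self):
        # distances: f0-f1 = 0.1, f0-f2 = 0.2, f1-f2 = 0.9
        absrho = np.array([[1.0, 0.9, 0.8],
                           [0.9, 1.0, 0.1],
                           [0.8, 0.1, 1.0]])
        net = _net_from_rho(absrho)
        got = {tuple(sorted(e)) for e in
               net.edges[["node_a", "node_b"]].itertuples(index=False)}
        assert got == {("m:f0", "m:f1"), ("m:f0", "m:f2")}
        assert net.edges["distance"].sum() == pytest.approx(0.3)

    def test_tree_properties(self):
        rng = np.random.default_rng(2)
        k = 9
        A = rng.uniform(0, 0.95, size=(k, k))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        net = _net_from_rho(A)
        assert net.is_tree
        assert net.edges.shape[0] == k - 1
        assert nx.is_connected(net.graph)
        assert nx.is_forest(net.graph)

    def test_matches_brute_force_over_all_spanning_trees(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(3, 7))
            A = rng.uniform(0, 0.99, size=(k, k))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            net = _net_from_rho(A)
            dist = 1.0 - np.abs(A)
            all_edges = list(itertools.combinations(range(k), 2))
            best = min(
                sum(dist[i, j] for i, j in subset)
                for subset in itertools.combinations(all_edges, k - 1)
                if nx.is_tree(nx.Graph(list(subset)))
            )
            assert net.edges["distance"].sum() == pytest.approx(best)

    def test_invariant_under_monotone_distance_transform(self):
        rng = np.random.default_rng(4)
        k = 8
        A = rng.uniform(0.05, 0.95, size=(k, k))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        net1 = _net_from_rho(A)
        # squash |rho| monotonically: order of 1 - |rho| is preserved
        net2 = _net_from_rho(1.0 - (1.0 - A) ** 2)
        e1 = {tuple(sorted(e)) for e in
              net1.edges[["node_a", "node_b"]].itertuples(index=False)}
        e2 = {tuple(sorted(e)) for e in
              net2.edges[["node_a", "node_b"]].itertuples(index=False)}
        assert e1 == e2

    def test_edge_annotations(self):
        absrho = np.array([[1.0, 0.5], [0.5, 1.0]])
        net = _net_from_rho(absrho)
        edge = net.edges.iloc[0]
        assert edge["p_adj"] == pytest.approx(min(1.0, 0.01 * 1))
        assert edge["width"] == pytest.approx(2.0)  # -log10(0.01)

    def test_all_degenerate_is_a_network_error(self):
        k = 3
        rho = pd.DataFrame(np.eye(k), index=list("abc"), columns=list("abc"))
        p = pd.DataFrame(np.ones((k, k)) - np.eye(k) * 1.0,
                         index=list("abc"), columns=list("abc"))
        p[:] = 1.0
        nodes = [FeatureNode("m", c, 0.0) for c in "abc"]
        with pytest.raises(NetworkError):
            build_mst(nodes, rho, p)


class TestLayout:
    def test_single_edge_distinct_and_deterministic(self):
        net = _net_from_rho(np.array([[1.0, 0.4], [0.4, 1.0]]))
        a = layout_network(net, seed=3)
        b = layout_network(net, seed=3)
        assert a == b
        assert a["m:f0"] != a["m:f1"]

    def test_large_tree_layout_is_finite(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(30, 226)))
        rho, p = spearman_matrix(df)
        nodes = [FeatureNode("m", str(c), 0.0) for c in df.columns]
        net = build_mst(nodes, rho, p)
        assert net.edges.shape[0] == 225
        coords = layout_network(net, seed=1)
        vals = np.array(list(coords.values()))
        assert np.isfinite(vals).all()
        assert len(coords) == 226
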