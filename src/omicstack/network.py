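"""Correlation networks over the reduced feature set.

The union of selected features across modalities is summarized as a
minimum spanning tree of pairwise Spearman association: edge *distance* is
1 - |rho| so strongly associated features sit close in the tree, each
retained edge carries the raw and Bonferroni-adjusted p-value, and the
display width of an edge is -log10(p) (capped).  Node size encodes the
univariate Spearman correlation of the feature with the outcome.  A
force-directed (Fruchterman-Reingold) layout is exported for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import NetworkError, ValidationError

#: -log10 p is capped at this display width (p floor 1e-12).
WIDTH_CAP = 12.0


@dataclass(frozen=True)
class FeatureNode:
    """A selected feature: identity plus univariate association with the
    outcome (node size is proportional to |outcome_rho|)."""

    modality_name: str
    feature_id: str
    outcome_rho: float = 0.0

    @property
    def key(self) -> str:
        return f"{self.modality_name}:{self.feature_id}"

    @property
    def size(self) -> float:
        return abs(self.outcome_rho)


def spearman_matrix(features) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p over the columns of `features`.

    Average-rank Spearman; p via the t-approximation for n > 10 and the
    exhaustive permutation distribution for n <= 10.  Pairs involving a
    constant (degenerate) column get rho = 0, p = 1.
    """
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(np.asarray(features, float))
    n, k = df.shape
    if k < 2:
        raise ValidationError("need at least 2 features")
    if n < 4:
        raise ValidationError("need at least 4 samples")
    if df.isna().to_numpy().any():
        raise ValidationError("spearman_matrix requires complete data")

    X = df.to_numpy(float)
    const = X.std(axis=0) == 0
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    Z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((Z ** 2).sum(axis=0))
    norms_safe = np.where(norms == 0, 1.0, norms)
    rho = (Z.T @ Z) / np.outer(norms_safe, norms_safe)
    rho = np.clip(rho, -1.0, 1.0)

    if n <= 10:
        from .crossval import _exact_spearman_p
        p = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                if not (const[i] or const[j]):
                    _, p[i, j] = _exact_spearman_p(X[:, i], X[:, j])
                p[j, i] = p[i, j]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.minimum(p, 1.0)

    rho[const, :] = 0.0
    rho[:, const] = 0.0
    p[const, :] = 1.0
    p[:, const] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = df.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def bonferroni(p: float, n: int) -> float:
    """Bonferroni adjustment: min(1, p * n)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must be in [0, 1]")
    if n < 1:
        raise ValidationError("n must be a positive integer")
    return min(1.0, p * n)


@dataclass
class CorrelationNetwork:
    """Nodes, annotated MST edges and the underlying graph."""

    nodes: list            # FeatureNode, in input order
    edges: pd.DataFrame    # node_a, node_b, rho, p, p_adj, width
    graph: nx.Graph
    is_tree: bool
    rho: pd.DataFrame      # full matrices retained so alternative edge
    p: pd.DataFrame        # weightings remain recomputable

    def node_table(self, layout: dict | None = None) -> pd.DataFrame:
        rows = []
        for nd in self.nodes:
            row = {"node": nd.key, "modality": nd.modality_name,
                   "feature_id": nd.feature_id, "outcome_rho": nd.outcome_rho,
                   "size": nd.size}
            if layout is not None:
                row["x"], row["y"] = layout[nd.key]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_mst(nodes: list, rho: pd.DataFrame, p: pd.DataFrame,
              adjust_by: str = "pairs") -> CorrelationNetwork:
    """Minimum spanning tree of the complete association graph.

    Edge distance is ``1 - |rho|`` (strong association = short edge).  Ties
    in distance are broken by lexicographic (node_a, node_b) order so the
    tree is deterministic.  Retained edges carry rho, the raw p, the
    Bonferroni-adjusted p, and the display width ``-log10(p)`` capped at
    ``WIDTH_CAP``.  ``adjust_by`` sets the Bonferroni denominator: the
    number of node *pairs* tested (default, conservative) or the number of
    *features* (nodes).
    """
    if adjust_by not in ("pairs", "features"):
        raise ValidationError(f"unknown adjust_by {adjust_by!r}")
    if len(nodes) < 2:
        raise ValidationError("need at least 2 nodes")
    keys = [nd.key for nd in nodes]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (modality, feature) nodes")
    labels = list(rho.columns)
    if len(labels) != len(nodes):
        raise ValidationError("rho matrix does not match the node list")

    R = rho.to_numpy(float)
    P = p.to_numpy(float)
    off = ~np.eye(len(labels), dtype=bool)
    if np.all(R[off] == 0.0) and np.all(P[off] == 1.0):
        raise NetworkError("all pairwise correlations are degenerate")

    G = nx.Graph()
    for nd in nodes:
        G.add_node(nd.key, modality=nd.modality_name, feature_id=nd.feature_id,
                   outcome_rho=float(nd.outcome_rho), size=float(nd.size))
    n_tests = (len(nodes) * (len(nodes) - 1) // 2 if adjust_by == "pairs"
               else len(nodes))
    # lexicographic insertion order makes Kruskal's stable sort break
    # distance ties deterministically
    pairs = sorted(
        (tuple(sorted((keys[i], keys[j]))), i, j)
        for i in range(len(nodes)) for j in range(i + 1, len(nodes))
    )
    for _, i, j in pairs:
        r, pv = float(R[i, j]), float(P[i, j])
        G.add_edge(
            keys[i], keys[j],
            weight=1.0 - abs(r), rho=r, p=pv,
            p_adj=bonferroni(pv, n_tests),
            width=min(-math.log10(max(pv, 10.0 ** -WIDTH_CAP)), WIDTH_CAP),
        )
    T = nx.minimum_spanning_tree(G, weight="weight", algorithm="kruskal")

    rows = [
        {"node_a": a, "node_b": b, "rho": d["rho"], "p": d["p"],
         "p_adj": d["p_adj"], "width": d["width"],
         "distance": d["weight"]}
        for a, b, d in sorted(T.edges(data=True))
    ]
    edges = pd.DataFrame(rows)
    is_tree = T.number_of_edges() == len(nodes) - 1 and nx.is_connected(T)
    return CorrelationNetwork(nodes=list(nodes), edges=edges, graph=T,
                              is_tree=is_tree, rho=rho, p=p)


def layout_network(network: CorrelationNetwork, seed: int = 0) -> dict:
    """Fruchterman-Reingold (force-directed) 2D coordinates per node key.

    Deterministic under `seed`; purely for export and plotting.
    """
    pos = nx.spring_layout(network.graph, seed=seed)
    return {k: (float(v[0]), float(v[1])) for k, v in pos.items()}
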