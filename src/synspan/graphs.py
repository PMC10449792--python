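"""Correlation and nearest-neighbour graphs over mean-expression vectors.

Nodes are labelled mean-expression vectors (cluster x species profiles,
or per-subject per-cluster means).  The correlation graph keeps edges
whose Pearson non-correlation test survives Bonferroni correction AND
whose absolute coefficient exceeds the global mean |r| over all node
pairs; the nearest-neighbour graph weights edges by one minus the
max-normalised Euclidean distance and keeps those above the mean weight.
Layouts use the force-directed Fruchterman-Reingold algorithm with a
fixed seed for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GraphSpec:
    """A built graph: node vectors, weighted edges, thresholds, layout."""

    node_labels: list
    node_vectors: np.ndarray
    edges: pd.DataFrame              # columns i, j, weight [, r, p, p_adj], retained
    kind: str
    alpha: float | None = None
    global_mean_cut: float | None = None
    layout: dict | None = None
    layout_seed: int | None = None
    node_attrs: dict = field(default_factory=dict)

    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)

    def to_networkx(self, retained_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        for idx, label in enumerate(self.node_labels):
            attrs = {k: v[idx] for k, v in self.node_attrs.items()}
            g.add_node(label, **attrs)
        edges = self.retained_edges() if retained_only else self.edges
        for row in edges.itertuples(index=False):
            g.add_edge(self.node_labels[int(row.i)], self.node_labels[int(row.j)],
                       weight=float(row.weight))
        return g

    def to_graphml(self, path, retained_only: bool = True) -> None:
        nx.write_graphml(self.to_networkx(retained_only), path)

    def to_json(self, path, retained_only: bool = True) -> None:
        g = self.to_networkx(retained_only)
        payload = nx.node_link_data(g, edges="links")
        if self.layout is not None:
            for node in payload["nodes"]:
                if node["id"] in self.layout:
                    node["x"], node["y"] = map(float, self.layout[node["id"]])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def edge_table_csv(self, path) -> None:
        out = self.edges.copy()
        out.insert(0, "node_i", [self.node_labels[int(i)] for i in out["i"]])
        out.insert(1, "node_j", [self.node_labels[int(j)] for j in out["j"]])
        out.to_csv(path, index=False, float_format="%.6g")


def _as_matrix(vectors) -> tuple[list, np.ndarray]:
    if isinstance(vectors, pd.DataFrame):
        return list(vectors.index), vectors.to_numpy(dtype=float)
    arr = np.asarray(vectors, dtype=float)
    return list(range(len(arr))), arr


def correlation_graph(vectors, alpha: float = 0.05) -> GraphSpec:
    """All-pairs Pearson correlation graph with Bonferroni + mean-|r| cut.

    Edge weight is |r|.  The Bonferroni family is all node pairs; the
    mean-|r| threshold is computed over all (finite) pairs before any
    significance filtering.  A zero-variance node has undefined
    correlations and is left isolated with a warning.
    """
    labels, X = _as_matrix(vectors)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 nodes")
    if X.shape[1] < 3:
        raise ValueError("need vectors of length >= 3")
    variances = X.std(axis=1)
    m = n * (n - 1) // 2
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if variances[i] == 0 or variances[j] == 0:
                logger.warning("zero-variance node %s or %s; edge undefined",
                               labels[i], labels[j])
                rows.append({"i": i, "j": j, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(X[i], X[j])
            rows.append({"i": i, "j": j, "r": float(r), "p": float(p)})
    edges = pd.DataFrame(rows)
    edges["weight"] = edges["r"].abs()
    edges["p_adj"] = np.minimum(edges["p"] * m, 1.0)
    mean_cut = float(edges["weight"].mean(skipna=True))
    edges["retained"] = (edges["p_adj"] < alpha) & (edges["weight"] > mean_cut)
    edges["retained"] = edges["retained"].fillna(False)
    return GraphSpec(node_labels=labels, node_vectors=X, edges=edges,
                     kind="correlation", alpha=alpha, global_mean_cut=mean_cut)


def nearest_neighbor_graph(vectors, normalization: str = "max") -> GraphSpec:
    """Similarity graph: weight = 1 - normalised Euclidean distance.

    ``normalization="max"`` divides pairwise distances by the maximum
    pairwise distance (so the farthest pair has weight 0); ``"z"``
    standardises each coordinate before computing distances, then scales
    by the max.  Edges with weight above the mean weight are retained.
    All-identical nodes give a complete graph of weight 1.
    """
    labels, X = _as_matrix(vectors)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    if normalization == "z":
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    elif normalization != "max":
        raise ValueError(f"unknown normalization {normalization!r}")
    rows = []
    dmax = 0.0
    dists = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(X[i] - X[j]))
            dists[(i, j)] = d
            dmax = max(dmax, d)
    for (i, j), d in dists.items():
        w = 1.0 if dmax == 0 else 1.0 - d / dmax
        rows.append({"i": i, "j": j, "distance": d, "weight": w})
    edges = pd.DataFrame(rows)
    mean_cut = float(edges["weight"].mean())
    edges["retained"] = edges["weight"] > mean_cut
    if dmax == 0:
        edges["retained"] = True  # degenerate: complete graph, weight 1
        mean_cut = 0.0
    return GraphSpec(node_labels=labels, node_vectors=X, edges=edges,
                     kind="nearest_neighbor", global_mean_cut=mean_cut)


def fr_layout(graph: GraphSpec, seed: int = 0) -> dict:
    """Deterministic weight-aware Fruchterman-Reingold layout."""
    g = graph.to_networkx(retained_only=True)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_nodes() == 1:
        pos = {next(iter(g.nodes)): np.zeros(2)}
    else:
        pos = nx.spring_layout(g, weight="weight", seed=seed)
    graph.layout = {k: np.asarray(v, dtype=float) for k, v in pos.items()}
    graph.layout_seed = seed
    return graph.layout


def species_cluster_profiles(table, labels) -> pd.DataFrame:
    """(cluster, species) mean-expression node vectors for graph building."""
    df = table.data.copy()
    df["_cluster"] = np.asarray(labels)
    prof = df.groupby(["_cluster", "species"], sort=True)[table.marker_names].mean()
    prof.index = [f"{c}|{s}" for c, s in prof.index]
    return prof
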