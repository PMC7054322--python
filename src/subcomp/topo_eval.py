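"""Structural evaluation of a sub-compartment assignment.

Embedding-space quality is scored with the silhouette index and a
Davies-Bouldin variant whose cluster dispersion and separation are both
mean pairwise distances (within-cluster pairs and between-cluster
pairs respectively) rather than the centroid-based classic. Network
topology of each intra-sub-compartment, inter-chromosomal subgraph is
summarized by closeness and betweenness centrality and the Barrat
weighted clustering coefficient; assignments from two methods are
compared metric-by-metric with a two-sided Mann-Whitney test.

Shortest paths use hop counts by default; ``weighted_mode="inverse-weight"``
uses 1/w_ij as the edge length so that strong contacts are short.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import silhouette_samples

from .clustering import SubCompartmentAssignment
from .hic_graph import ContactGraph


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette s_i = (b_i - a_i)/max(a_i, b_i) and its mean.

    a_i is the mean Euclidean distance to the point's own cluster
    (excluding itself), b_i the smallest mean distance to another
    cluster; a singleton cluster scores 0.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = silhouette_samples(points, labels, metric="euclidean")
    return s, float(s.mean())


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with all-pairs distances.

    d_i = mean pairwise distance within cluster i; d_ij = mean distance
    over all between-cluster pairs; D_ij = (d_i + d_j)/d_ij;
    DBI = (1/k) sum_i max_{j != i} D_ij.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = [u for u in dict.fromkeys(labels.tolist())]
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    groups = [points[labels == u] for u in uniq]
    d_within = np.array([
        float(pdist(g).mean()) if len(g) > 1 else 0.0 for g in groups
    ])
    dbi = 0.0
    for a in range(k):
        best = -np.inf
        for b in range(k):
            if a == b:
                continue
            d_ab = float(cdist(groups[a], groups[b]).mean())
            if d_ab == 0:
                raise ValueError("coincident clusters: between-cluster distance 0")
            best = max(best, (d_within[a] + d_within[b]) / d_ab)
        dbi += best
    return dbi / k


def compartment_subgraph(graph: ContactGraph,
                         assignment: SubCompartmentAssignment,
                         label: str) -> ContactGraph:
    """Induced subgraph on the bins carrying ``label``; weights kept."""
    if label not in assignment.present_labels:
        raise KeyError(f"unknown label {label!r}")
    keep = np.zeros(graph.n_nodes, dtype=bool)
    keep[assignment.members(label)] = True
    mask = keep[graph.edge_i] & keep[graph.edge_j]
    return ContactGraph(graph.bins, graph.edge_i[mask], graph.edge_j[mask],
                        graph.edge_w[mask])


def _to_networkx(graph: ContactGraph, nodes: list[int] | None = None) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes if nodes is not None else range(graph.n_nodes))
    for i, j, w in graph.edges():
        g.add_edge(i, j, weight=w, dist=1.0 / w)
    return g


def _check_mode(weighted_mode: str) -> str | None:
    if weighted_mode == "hop":
        return None
    if weighted_mode == "inverse-weight":
        return "dist"
    raise ValueError(f"weighted_mode must be 'hop' or 'inverse-weight', got {weighted_mode!r}")


def closeness(graph: ContactGraph, weighted_mode: str = "hop",
              nodes: list[int] | None = None) -> dict[int, float]:
    """Closeness centrality C(u) = (n-1)/sum_v d(v,u).

    Computed within u's component and scaled by the component fraction
    (Wasserman-Faust), so disconnected subgraphs remain comparable.
    """
    g = _to_networkx(graph, nodes)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    dist = _check_mode(weighted_mode)
    return {int(n): float(c) for n, c in
            nx.closeness_centrality(g, distance=dist, wf_improved=True).items()}


def betweenness(graph: ContactGraph, weighted_mode: str = "hop",
                normalized: bool = False,
                nodes: list[int] | None = None) -> dict[int, float]:
    """Betweenness C_B(u) = sum over pairs of sigma(s,t|u)/sigma(s,t).

    Endpoints excluded; each unordered pair counted once; unnormalized
    by default (a normalized option divides by (n-1)(n-2)/2).
    """
    g = _to_networkx(graph, nodes)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    dist = _check_mode(weighted_mode)
    return {int(n): float(c) for n, c in
            nx.betweenness_centrality(g, weight=dist, normalized=normalized).items()}


def clustering_coefficient(graph: ContactGraph, node: int) -> float:
    """Barrat weighted clustering coefficient of one node.

    c_u = 1/(s_u (k_u - 1)) * sum over ordered neighbor pairs (v, w)
    closing a triangle with u of (w_uv + w_uw)/2, where s_u is the
    strength and k_u the (unweighted) degree of u; with unit weights
    this reduces to the ordinary triplet ratio. Degree < 2 scores 0.
    """
    if not 0 <= node < graph.n_nodes:
        raise KeyError(f"node {node} not in graph")
    nbr: dict[int, float] = {}
    for i, j, w in graph.edges():
        if i == node:
            nbr[j] = w
        elif j == node:
            nbr[i] = w
    k_u = len(nbr)
    if k_u < 2:
        return 0.0
    s_u = sum(nbr.values())
    adj = {(i, j) for i, j, _ in graph.edges()} | {(j, i) for i, j, _ in graph.edges()}
    nbrs = sorted(nbr)
    tri = 0.0
    for a in range(len(nbrs)):
        for b in range(a + 1, len(nbrs)):
            v, w_ = nbrs[a], nbrs[b]
            if (v, w_) in adj:  # ordered pairs: each unordered pair twice
                tri += nbr[v] + nbr[w_]
    return tri / (s_u * (k_u - 1))


def compare_methods(values_a: np.ndarray, values_b: np.ndarray
                    ) -> tuple[float, float]:
    """Median difference and two-sided Mann-Whitney p between two metric samples.

    Exact enumeration when both samples have n <= 8, tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    method = "exact" if (a.size <= 8 and b.size <= 8 and
                         len(np.unique(np.concatenate([a, b]))) == a.size + b.size) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    delta = float(np.median(a) - np.median(b))
    return delta, float(res.pvalue)


@dataclass
class StructuralReport:
    """Embedding- and network-level summary of one assignment."""

    silhouette_per_node: np.ndarray
    silhouette_mean: float
    dbi: float
    per_compartment: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "silhouette_mean": self.silhouette_mean,
            "davies_bouldin": self.dbi,
            "per_compartment": self.per_compartment,
        }


def structural_report(emb, assignment: SubCompartmentAssignment,
                      graph: ContactGraph,
                      weighted_mode: str = "hop") -> StructuralReport:
    """Silhouette, DBI, and mean centralities of each intra-compartment subgraph."""
    order = [int(n) for n in emb.node_ids]
    labels = np.array([assignment.label_of(n) for n in order])
    s_i, s_mean = silhouette(emb.vectors, labels)
    dbi = davies_bouldin(emb.vectors, labels)
    per: dict[str, dict[str, float]] = {}
    for lab in assignment.present_labels:
        sub = compartment_subgraph(graph, assignment, lab)
        members = assignment.members(lab)
        clo = closeness(sub, weighted_mode, nodes=members)
        bet = betweenness(sub, weighted_mode, nodes=members)
        cc = [clustering_coefficient(sub, n) for n in members]
        per[lab] = {
            "n_bins": float(len(members)),
            "mean_closeness": float(np.mean(list(clo.values()))),
            "mean_betweenness": float(np.mean(list(bet.values()))),
            "mean_clustering_coefficient": float(np.mean(cc)),
        }
    return StructuralReport(s_i, s_mean, dbi, per)
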