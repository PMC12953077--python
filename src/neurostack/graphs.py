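"""Graph-theoretical features of weighted structural connectomes.

A subject's connectome is an undirected weighted graph G = (V, E) whose
82 nodes are atlas regions and whose edge weights are connection
strengths (fiber-count-like, arbitrary positive units).  From it we
compute 7 nodal metrics per region plus 17 global metrics — 591 features
for the 82-region atlas, 7n + 17 in general.

Conventions (weighted variants):

* clustering coefficient (CC): geometric-mean weighted clustering;
* degree centrality (DC): degree / (n - 1);
* eigenvector centrality (EC): leading eigenvector of the weighted
  adjacency, unit 2-norm, non-negative orientation;
* closeness (CClo) and betweenness (BC): shortest paths on inverse-weight
  distances, standard normalizations (Wasserman-Faust scaling for
  closeness on disconnected graphs);
* node strength (NS): sum of incident weights;
* PageRank (PR): damping 0.85 on weighted transitions.

Shortest-path global metrics (CPL, diameter, efficiency, small-world
ratio) also use inverse-weight distances; CPL and diameter are taken on
the largest connected component and efficiency counts unreachable pairs
as zero, so disconnected inputs stay finite (a warning is emitted).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ConnectivityMatrix
from .regions import GLOBAL_METRICS, NODAL_METRICS, gt_feature_names


class GraphMetricError(ValueError):
    """Invalid graph input or undefined metric."""


def build_graph(matrix: ConnectivityMatrix | np.ndarray,
                labels: list[str] | None = None) -> nx.Graph:
    """Build an undirected weighted graph; edge (i, j) present iff
    weight > 0."""
    if isinstance(matrix, ConnectivityMatrix):
        labels = matrix.labels
        w = matrix.weights
    else:
        w = np.asarray(matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphMetricError("adjacency must be square")
        if not np.allclose(w, w.T):
            raise GraphMetricError("adjacency must be symmetric")
        if (w < 0).any():
            raise GraphMetricError("adjacency must be non-negative")
        if np.diagonal(w).any():
            raise GraphMetricError("adjacency must have zero diagonal")
        if labels is None:
            labels = [f"n{i}" for i in range(w.shape[0])]
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(labels[i], labels[j], weight=float(w[i, j]))
    return g


def to_distance_weights(graph: nx.Graph) -> nx.Graph:
    """Attach ``distance`` = 1 / weight to every edge (weights are
    connection strengths, so stronger connections are shorter)."""
    for _, _, d in graph.edges(data=True):
        if d["weight"] <= 0:
            raise GraphMetricError("zero-weight edge present; edges with "
                                   "weight 0 must be absent")
        d["distance"] = 1.0 / d["weight"]
    return graph


def _eigenvector_centrality(graph: nx.Graph) -> dict:
    nodes = list(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, int(np.argmax(vals))]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector of the dominant component
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    return dict(zip(nodes, v))


def nodal_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node metric table, columns ordered CC, DC, EC, CClo, BC, NS, PR."""
    to_distance_weights(graph)
    nodes = list(graph.nodes)
    n = len(nodes)
    cc = nx.clustering(graph, weight="weight")
    dc = nx.degree_centrality(graph) if n > 1 else {u: 0.0 for u in nodes}
    ec = _eigenvector_centrality(graph)
    cclo = nx.closeness_centrality(graph, distance="distance")
    bc = nx.betweenness_centrality(graph, weight="distance", normalized=True)
    ns = dict(graph.degree(weight="weight"))
    if graph.number_of_edges() > 0:
        pr = nx.pagerank(graph, alpha=0.85, weight="weight")
    else:
        pr = {u: 1.0 / n for u in nodes}
    cols = {"CC": cc, "DC": dc, "EC": ec, "CClo": cclo, "BC": bc,
            "NS": ns, "PR": pr}
    return pd.DataFrame({m: [cols[m][u] for u in nodes]
                         for m in NODAL_METRICS}, index=nodes)


def _rewired_reference(graph: nx.Graph,
                       rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring of the binary structure with the
    original weight multiset re-assigned by random permutation."""
    ref = nx.Graph()
    ref.add_nodes_from(graph.nodes)
    ref.add_edges_from(graph.edges)
    m = ref.number_of_edges()
    if m >= 2 and ref.number_of_nodes() >= 4:
        try:
            nx.double_edge_swap(ref, nswap=10 * m, max_tries=200 * m,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXException:
            pass  # too few swappable pairs; keep partial rewiring
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)])
    perm = rng.permutation(len(weights))
    for (u, v), k in zip(ref.edges, perm):
        ref[u][v]["weight"] = float(weights[k])
    return ref


def _path_stats(graph: nx.Graph) -> tuple[float, float, float]:
    """(global efficiency, CPL, diameter) on inverse-weight distances.

    Efficiency averages 1/d over all ordered pairs with 0 for unreachable
    pairs; CPL and diameter are computed on the largest component.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components, shortest_path

    to_distance_weights(graph)
    n = graph.number_of_nodes()
    if n < 2 or graph.number_of_edges() == 0:
        return 0.0, 0.0, 0.0
    adj = csr_matrix(nx.to_numpy_array(graph, weight="distance"))
    dist = shortest_path(adj, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(dist) & off
    efficiency = float((1.0 / dist[reachable]).sum()) / (n * (n - 1))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn("graph is disconnected; CPL/diameter computed on the "
                      "largest component", stacklevel=2)
    giant = labels == np.bincount(labels).argmax()
    if giant.sum() < 2:
        return efficiency, 0.0, 0.0
    sub = dist[np.ix_(giant, giant)][np.eye(int(giant.sum()), dtype=bool)
                                     == False]  # noqa: E712
    return efficiency, float(sub.mean()), float(sub.max())


def global_metrics(graph: nx.Graph, seed: int = 0,
                   n_random_refs: int = 10) -> dict[str, float]:
    """The 17 global metrics (see module docstring for conventions).

    Small-worldness is the ratio (C/C_rand)/(L/L_rand) against
    ``n_random_refs`` degree-preserving rewired references (seeded).
    Degree assortativity is 0 by convention on degree-regular graphs,
    where its correlation is undefined.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise GraphMetricError("triangle-based global metrics undefined "
                               "for n < 3")
    nodal = nodal_metrics(graph)
    m = graph.number_of_edges()
    out: dict[str, float] = {}
    out["density"] = nx.density(graph)
    if m > 0:
        comms = nx.community.greedy_modularity_communities(graph,
                                                           weight="weight")
        out["modularity"] = nx.community.modularity(graph, comms,
                                                    weight="weight")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = nx.degree_assortativity_coefficient(graph,
                                                         weight="weight")
        out["assortativity"] = float(assort) if np.isfinite(assort) else 0.0
    else:
        out["modularity"] = 0.0
        out["assortativity"] = 0.0
    out["transitivity"] = nx.transitivity(graph)
    eff, cpl, diam = _path_stats(graph)
    out["global_efficiency"] = eff
    out["CPL"] = cpl
    out["diameter"] = diam

    c_obs = float(nodal["CC"].mean())
    sw = 0.0
    if m > 1 and cpl > 0 and n_random_refs > 0:
        rng = np.random.default_rng(seed)
        c_rand, l_rand = [], []
        for _ in range(n_random_refs):
            ref = _rewired_reference(graph, rng)
            c_rand.append(float(np.mean(list(
                nx.clustering(ref, weight="weight").values()))))
            _, ref_cpl, _ = _path_stats(ref)
            l_rand.append(ref_cpl)
        c_bar, l_bar = float(np.mean(c_rand)), float(np.mean(l_rand))
        if c_bar > 0 and l_bar > 0:
            sw = (c_obs / c_bar) / (cpl / l_bar)
    out["SW"] = sw

    degrees = np.array([d for _, d in graph.degree()])
    _, counts = np.unique(degrees, return_counts=True)
    p = counts / counts.sum()
    out["DegEnt"] = float(-(p * np.log(p)).sum())
    adj = nx.to_numpy_array(graph, weight="weight")
    out["SpecRad"] = float(np.max(np.abs(np.linalg.eigvalsh(adj)))) if m else 0.0
    out["avgDeg"] = float(degrees.mean())
    for metric in NODAL_METRICS:
        out[f"avg{metric}"] = float(nodal[metric].mean())
    return {k: out[k] for k in GLOBAL_METRICS}


def extract_gt_features(matrix: ConnectivityMatrix | np.ndarray,
                        seed: int = 0,
                        labels: list[str] | None = None,
                        n_random_refs: int = 10) -> pd.Series:
    """574 nodal + 17 global features in the frozen name order
    (``<metric>_<region>`` blocks, metric-major, then globals)."""
    graph = build_graph(matrix, labels=labels)
    nodes = list(graph.nodes)
    nodal = nodal_metrics(graph)
    glob = global_metrics(graph, seed=seed, n_random_refs=n_random_refs)
    values = np.concatenate(
        [nodal[m].to_numpy() for m in NODAL_METRICS]
        + [np.array([glob[g] for g in GLOBAL_METRICS])])
    return pd.Series(values, index=gt_feature_names(nodes))


def gt_feature_table(matrices, seed: int = 0, subject_ids=None,
                     n_random_refs: int = 10) -> pd.DataFrame:
    """Stack per-subject GT vectors into a subjects x 591 table."""
    rows = [extract_gt_features(m, seed=seed, n_random_refs=n_random_refs)
            for m in matrices]
    df = pd.DataFrame(rows)
    if subject_ids is not None:
        df.index = pd.Index(list(subject_ids), name="subject_id")
    return df
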