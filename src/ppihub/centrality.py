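"""Ten node-centrality indexes for hub detection on PPI networks.

The ensemble follows the CytoHubba convention: degree, betweenness, stress,
eccentricity (reported as its reciprocal so that larger = more central),
radiality, bottleneck, maximum neighborhood component (MNC), density of the
maximum neighborhood component (DMNC), maximal clique centrality (MCC) and
edge percolation component (EPC).

All indexes are defined on simple undirected unweighted graphs. Shortest
paths are unweighted BFS distances; unordered node pairs are counted once.
Pair- and distance-based quantities are computed within connected
components; conventions for isolated nodes are noted per function.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "INDEX_COLUMNS",
    "EpcConfig",
    "degree",
    "betweenness",
    "stress",
    "eccentricity_score",
    "radiality",
    "bottleneck",
    "mnc",
    "dmnc",
    "mcc",
    "epc",
    "compute_all_centralities",
]

#: Fixed column order of the centrality table.
INDEX_COLUMNS = (
    "degree",
    "betweenness",
    "stress",
    "eccentricity",
    "radiality",
    "bottleneck",
    "mnc",
    "dmnc",
    "mcc",
    "epc",
)


@dataclass(frozen=True)
class EpcConfig:
    """Monte-Carlo parameters for the edge percolation component index."""

    n_iterations: int = 1000
    retain_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.retain_probability <= 1.0:
            raise ValueError("retain_probability must be in [0, 1]")


def _nodes_sorted(G: nx.Graph) -> list:
    return sorted(G.nodes, key=str)


def degree(G: nx.Graph) -> dict:
    """Number of neighbors of each node."""
    return {v: d for v, d in G.degree()}


def betweenness(G: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness.

    For node v: sum over unordered pairs {s, t} (s, t != v) of the fraction
    of shortest s-t paths passing through v. Endpoints are excluded, so
    leaves score 0 and every node of a complete graph scores 0.
    """
    return nx.betweenness_centrality(G, normalized=False)


def _bfs_dag(G: nx.Graph, s):
    """BFS from s: order visited, predecessor lists, path counts, distances."""
    dist = {s: 0}
    sigma = {s: 1.0}
    preds: dict = {s: []}
    order = [s]
    q = deque([s])
    while q:
        u = q.popleft()
        for w in G.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                preds[w] = []
                order.append(w)
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
                preds[w].append(u)
    return order, preds, sigma, dist


def stress(G: nx.Graph) -> dict:
    """Number of shortest paths between other node pairs passing through v.

    Unlike betweenness, every shortest path counts 1 regardless of how many
    shortest paths its endpoint pair has. Computed by a Brandes-style
    accumulation: from root s, delta(v) = sigma_s(v) * sum over successors w
    of (1 + delta(w) / sigma_s(w)); summing over all roots counts each
    unordered pair twice, hence the final halving.
    """
    acc = dict.fromkeys(G, 0.0)
    for s in G:
        order, preds, sigma, _ = _bfs_dag(G, s)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] * (1.0 + delta[w] / sigma[w])
        for v in order:
            if v != s:
                acc[v] += delta[v]
    return {v: round(x / 2.0) for v, x in acc.items()}


def eccentricity_score(G: nx.Graph) -> dict:
    """Reciprocal eccentricity: 1 / max distance to any node in v's component.

    Raw eccentricity is small for central nodes; the composite score rewards
    large values, so the reciprocal is reported (values in (0, 1]; isolated
    nodes score 1 by convention).
    """
    out = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 1.0
            continue
        for v, e in nx.eccentricity(sub).items():
            out[v] = 1.0 / e
    return out


def radiality(G: nx.Graph) -> dict:
    """Component-diameter-shifted closeness.

    radiality(v) = sum_w (diam + 1 - d(v, w)) / (n_c - 1) over the other
    nodes w of v's component of size n_c; equals diam + 1 - (mean distance).
    Isolated nodes score 0.
    """
    out = {}
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        sub = G.subgraph(comp)
        n_c = len(comp)
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            total = sum(diam + 1 - d for w, d in dists[v].items() if w != v)
            out[v] = total / (n_c - 1)
    return out


def bottleneck(G: nx.Graph) -> dict:
    """BottleNeck index: tree-based traffic concentration.

    For each root s of v's component, grow a BFS shortest-path tree (each
    node's parent is its lexicographically smallest predecessor, for
    determinism) and let p_s(v) be the size of v's subtree, v included.
    bottleneck(v) counts the roots s != v with p_s(v) > n_c / 4.
    """
    out = dict.fromkeys(G, 0)
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            continue
        sub = G.subgraph(comp)
        n_c = len(comp)
        threshold = n_c / 4.0
        for s in comp:
            order, preds, _, _ = _bfs_dag(sub, s)
            parent = {
                v: min(ps, key=str) for v, ps in preds.items() if ps
            }
            size = dict.fromkeys(order, 1)
            for v in reversed(order):
                if v in parent:
                    size[parent[v]] += size[v]
            for v in order:
                if v != s and size[v] > threshold:
                    out[v] += 1
    return out


def _largest_neighborhood_component(G: nx.Graph, v):
    """Largest connected component of the subgraph induced by v's neighbors.

    Ties by node count are broken by edge count, then by sorted node labels,
    so DMNC is deterministic.
    """
    nbrs = list(G.neighbors(v))
    if not nbrs:
        return None
    sub = G.subgraph(nbrs)
    best = None
    for comp in nx.connected_components(sub):
        cand = sub.subgraph(comp)
        key = (
            cand.number_of_nodes(),
            cand.number_of_edges(),
            tuple(sorted((str(n) for n in comp), reverse=True)),
        )
        if best is None or key > best[0]:
            best = (key, cand)
    return best[1]


def mnc(G: nx.Graph) -> dict:
    """Maximum neighborhood component: node count of the largest connected
    component among v's neighbors (v excluded). 0 for isolated nodes."""
    out = {}
    for v in G:
        comp = _largest_neighborhood_component(G, v)
        out[v] = 0 if comp is None else comp.number_of_nodes()
    return out


def dmnc(G: nx.Graph, epsilon: float = 1.7) -> dict:
    """Density of the maximum neighborhood component: |E(N_v)| / |V(N_v)|^eps.

    N_v is the component measured by MNC; eps defaults to 1.7, the constant
    of the CytoHubba formulation. 0 when the component has no edges.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    out = {}
    for v in G:
        comp = _largest_neighborhood_component(G, v)
        if comp is None or comp.number_of_edges() == 0:
            out[v] = 0.0
        else:
            out[v] = comp.number_of_edges() / comp.number_of_nodes() ** epsilon
    return out


def mcc(G: nx.Graph) -> dict:
    """Maximal clique centrality: sum of (|C| - 1)! over maximal cliques C
    containing v. Equals the degree when v's neighborhood has no edges
    (every incident edge is then a maximal 2-clique)."""
    out = dict.fromkeys(G, 0)
    for clique in nx.find_cliques(G):
        if len(clique) < 2:
            continue  # isolated node: contributes 0
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def epc(G: nx.Graph, config: EpcConfig | None = None) -> dict:
    """Edge percolation component: Monte-Carlo mean component size.

    Each edge is retained independently with ``retain_probability``; epc(v)
    is the average, over ``n_iterations`` percolated copies, of the size of
    the connected component containing v. Values lie in [1, n] and are
    bit-reproducible for a fixed seed (edges are processed in sorted order).
    """
    if config is None:
        config = EpcConfig()
    nodes = _nodes_sorted(G)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = sorted(
        ((idx[u], idx[v]) for u, v in G.edges),
        key=lambda e: (min(e), max(e)),
    )
    m = len(edges)
    rng = np.random.default_rng(config.seed)
    acc = np.zeros(n)
    if m:
        ei = np.array([e[0] for e in edges])
        ej = np.array([e[1] for e in edges])
    for _ in range(config.n_iterations):
        if m:
            keep = rng.random(m) < config.retain_probability
            data = np.ones(int(keep.sum()))
            adj = coo_matrix(
                (data, (ei[keep], ej[keep])), shape=(n, n)
            )
            _, labels = _cc(adj, directed=False)
        else:
            labels = np.arange(n)
        acc += np.bincount(labels, minlength=labels.max() + 1)[labels]
    means = acc / config.n_iterations
    return {v: float(means[idx[v]]) for v in nodes}


def compute_all_centralities(
    G: nx.Graph,
    epc_config: EpcConfig | None = None,
    dmnc_epsilon: float = 1.7,
) -> pd.DataFrame:
    """Compute the full 10-index table for every node.

    Returns a DataFrame indexed by node (sorted by label) with the columns of
    :data:`INDEX_COLUMNS`, all finite and >= 0. Requires at least 2 nodes.
    """
    if G.number_of_nodes() < 2:
        raise ValueError("network must have at least 2 nodes")
    values = {
        "degree": degree(G),
        "betweenness": betweenness(G),
        "stress": stress(G),
        "eccentricity": eccentricity_score(G),
        "radiality": radiality(G),
        "bottleneck": bottleneck(G),
        "mnc": mnc(G),
        "dmnc": dmnc(G, epsilon=dmnc_epsilon),
        "mcc": mcc(G),
        "epc": epc(G, epc_config),
    }
    nodes = _nodes_sorted(G)
    table = pd.DataFrame(
        {col: [values[col][v] for v in nodes] for col in INDEX_COLUMNS},
        index=pd.Index(nodes, name="node"),
        dtype=float,
    )
    assert np.isfinite(table.to_numpy()).all()
    return table
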