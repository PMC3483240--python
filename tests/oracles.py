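"""Independent brute-force reference implementations for small graphs.

Everything here is written from the definitions, by explicit enumeration
(simple-path search, subset checks, union-find), deliberately avoiding the
algorithms used by the package so agreement is meaningful. Only usable on
small graphs.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def _neighbors(edges, v):
    for a, b in edges:
        if a == v:
            yield b
        elif b == v:
            yield a


def all_simple_paths(edges, s, t):
    """Every simple path from s to t, by depth-first enumeration."""
    paths = []

    def walk(path):
        head = path[-1]
        if head == t:
            paths.append(list(path))
            return
        for w in _neighbors(edges, head):
            if w not in path:
                path.append(w)
                walk(path)
                path.pop()

    walk([s])
    return paths


def shortest_paths(edges, s, t):
    """All shortest simple paths s -> t (empty list if disconnected)."""
    paths = all_simple_paths(edges, s, t)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def distance(edges, s, t):
    sp = shortest_paths(edges, s, t)
    return len(sp[0]) - 1 if sp else None


def components(nodes, edges):
    """Connected components by transitive closure over the edge list."""
    comps = []
    left = set(nodes)
    while left:
        seed = left.pop()
        comp = {seed}
        grew = True
        while grew:
            grew = False
            for a, b in edges:
                if a in comp and b not in comp:
                    comp.add(b)
                    grew = True
                if b in comp and a not in comp:
                    comp.add(a)
                    grew = True
        left -= comp
        comps.append(comp)
    return comps


def brute_degree(nodes, edges):
    return {v: sum(1 for _ in _neighbors(edges, v)) for v in nodes}


def brute_betweenness(nodes, edges):
    out = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(sorted(nodes, key=str), 2):
        sp = shortest_paths(edges, s, t)
        if not sp:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            out[v] += Fraction(through, len(sp))
    return {v: float(x) for v, x in out.items()}


def brute_stress(nodes, edges):
    out = dict.fromkeys(nodes, 0)
    for s, t in itertools.combinations(sorted(nodes, key=str), 2):
        for p in shortest_paths(edges, s, t):
            for v in p[1:-1]:
                out[v] += 1
    return out


def brute_eccentricity_score(nodes, edges):
    out = {}
    for v in nodes:
        dists = [distance(edges, v, w) for w in nodes if w != v]
        dists = [d for d in dists if d is not None]
        out[v] = 1.0 if not dists else 1.0 / max(dists)
    return out


def brute_radiality(nodes, edges):
    out = {}
    for comp in components(nodes, edges):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dmat = {
            (v, w): distance(edges, v, w)
            for v in comp
            for w in comp
            if v != w
        }
        diam = max(dmat.values())
        for v in comp:
            total = sum(diam + 1 - dmat[(v, w)] for w in comp if w != v)
            out[v] = total / (len(comp) - 1)
    return out


def brute_bottleneck(nodes, edges):
    out = dict.fromkeys(nodes, 0)
    for comp in components(nodes, edges):
        if len(comp) == 1:
            continue
        for s in comp:
            # shortest-path tree: parent = lexicographically smallest
            # predecessor on any shortest path from s
            parent = {}
            for v in comp:
                if v == s:
                    continue
                preds = {p[-2] for p in shortest_paths(edges, s, v)}
                parent[v] = min(preds, key=str)
            for v in comp:
                if v == s:
                    continue
                # subtree of v = nodes whose parent chain passes through v
                size = 0
                for w in comp:
                    if w == s:
                        continue
                    node = w
                    while node != s:
                        if node == v:
                            size += 1
                            break
                        node = parent[node]
                if size > len(comp) / 4:
                    out[v] += 1
    return out


def _is_clique(edges, group):
    eset = {frozenset(e) for e in edges}
    return all(
        frozenset((a, b)) in eset for a, b in itertools.combinations(group, 2)
    )


def brute_maximal_cliques(nodes, edges):
    """All maximal cliques by exhaustive subset enumeration."""
    nodes = sorted(nodes, key=str)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for group in itertools.combinations(nodes, r):
            if _is_clique(edges, group):
                cliques.append(frozenset(group))
    return [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]


def brute_mcc(nodes, edges):
    out = dict.fromkeys(nodes, 0)
    for c in brute_maximal_cliques(nodes, edges):
        if len(c) < 2:
            continue
        for v in c:
            out[v] += math.factorial(len(c) - 1)
    return out


def _neighborhood_components(nodes, edges, v):
    nbrs = set(_neighbors(edges, v))
    sub_edges = [e for e in edges if e[0] in nbrs and e[1] in nbrs]
    return [
        (comp, [e for e in sub_edges if e[0] in comp])
        for comp in components(nbrs, sub_edges)
    ]


def brute_mnc(nodes, edges):
    out = {}
    for v in nodes:
        comps = _neighborhood_components(nodes, edges, v)
        out[v] = max((len(c) for c, _ in comps), default=0)
    return out


def brute_dmnc(nodes, edges, epsilon=1.7):
    out = {}
    for v in nodes:
        comps = _neighborhood_components(nodes, edges, v)
        if not comps:
            out[v] = 0.0
            continue
        best = max(
            comps,
            key=lambda ce: (
                len(ce[0]),
                len(ce[1]),
                tuple(sorted(map(str, ce[0]), reverse=True)),
            ),
        )
        comp, ce = best
        out[v] = len(ce) / len(comp) ** epsilon if ce else 0.0
    return out


def exact_epc(nodes, edges, retain_probability):
    """Exact expected percolated-component size by enumerating all edge
    subsets (2^|E| terms)."""
    nodes = list(nodes)
    edges = list(edges)
    p = retain_probability
    out = dict.fromkeys(nodes, 0.0)
    for keep_mask in itertools.product([0, 1], repeat=len(edges)):
        kept = [e for e, keep in zip(edges, keep_mask) if keep]
        weight = math.prod(
            p if keep else 1 - p for keep in keep_mask
        )
        for comp in components(nodes, kept):
            for v in comp:
                out[v] += weight * len(comp)
    return out


def brute_k_clique_communities(nodes, edges, k):
    """CPM by explicit enumeration of all k-cliques and union-find over the
    share-(k-1)-nodes relation."""
    kcliques = [
        frozenset(group)
        for group in itertools.combinations(sorted(nodes, key=str), k)
        if _is_clique(edges, group)
    ]
    parent = list(range(len(kcliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) >= k - 1:
            parent[find(i)] = find(j)

    groups = {}
    for i, cl in enumerate(kcliques):
        groups.setdefault(find(i), set()).update(cl)
    return sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda c: (-len(c), tuple(sorted(map(str, c)))),
    )


def brute_hypergeom_upper_tail(k, n, K, N):
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(
            math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n)
        )
    return float(min(total, Fraction(1)))


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = pvals[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


# --- distance-matrix oracles -------------------------------------------------
# A second independent route for graphs where path enumeration is too slow
# (up to ~12 nodes): distances by boolean matrix powers, shortest-path counts
# by dynamic programming over distance layers, pair sums by the textbook
# sigma_st(v) = sigma_sv * sigma_vt combination rule.


def _dist_sigma_matrices(nodes, edges):
    import numpy as np

    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    inf = n + 1
    dist = np.full((n, n), inf, dtype=int)
    np.fill_diagonal(dist, 0)
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=bool)
    for d in range(1, n):
        power = power @ adj
        newly = power & ~reach
        dist[newly] = d
        reach |= newly
        if reach.all():
            break
    sigma = np.zeros((n, n), dtype=float)
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        for d in range(1, n):
            layer = np.where(dist[s] == d)[0]
            for v in layer:
                preds = np.where(adj[v] & (dist[s] == d - 1))[0]
                sigma[s, v] = sigma[s, preds].sum()
    return idx, adj, dist, sigma, inf


def dp_betweenness_and_stress(nodes, edges):
    import itertools

    nodes = list(nodes)
    idx, adj, dist, sigma, inf = _dist_sigma_matrices(nodes, edges)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(range(len(nodes)), 2):
        if dist[s, t] >= inf:
            continue
        for vi, v in enumerate(nodes):
            if vi in (s, t):
                continue
            if dist[s, vi] + dist[vi, t] == dist[s, t]:
                through = sigma[s, vi] * sigma[vi, t]
                bet[v] += through / sigma[s, t]
                stress[v] += int(round(through))
    return bet, stress


def dp_eccentricity_score(nodes, edges):
    nodes = list(nodes)
    idx, adj, dist, sigma, inf = _dist_sigma_matrices(nodes, edges)
    out = {}
    for vi, v in enumerate(nodes):
        finite = dist[vi][(dist[vi] < inf)]
        ecc = finite.max()
        out[v] = 1.0 if ecc == 0 else 1.0 / float(ecc)
    return out


def dp_radiality(nodes, edges):
    nodes = list(nodes)
    idx, adj, dist, sigma, inf = _dist_sigma_matrices(nodes, edges)
    out = {}
    for comp in components(nodes, edges):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        cidx = [idx[v] for v in comp]
        sub = dist[cidx][:, cidx]
        diam = int(sub.max())
        for v in comp:
            row = dist[idx[v], cidx]
            total = sum(diam + 1 - int(d) for d in row if d > 0)
            out[v] = total / (len(comp) - 1)
    return out


def dp_bottleneck(nodes, edges):
    nodes = list(nodes)
    idx, adj, dist, sigma, inf = _dist_sigma_matrices(nodes, edges)
    out = {v: 0 for v in nodes}
    for comp in components(nodes, edges):
        if len(comp) == 1:
            continue
        for s in comp:
            si = idx[s]
            parent = {}
            for v in comp:
                if v == s:
                    continue
                vi = idx[v]
                preds = [
                    w for w in comp
                    if adj[vi, idx[w]] and dist[si, idx[w]] == dist[si, vi] - 1
                ]
                parent[v] = min(preds, key=str)
            for v in comp:
                if v == s:
                    continue
                size = 0
                for w in comp:
                    if w == s:
                        continue
                    node = w
                    while node != s:
                        if node == v:
                            size += 1
                            break
                        node = parent[node]
                if size > len(comp) / 4:
                    out[v] += 1
    return out
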