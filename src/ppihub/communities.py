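"""Overlapping community detection by clique percolation (CPM).

A k-clique community is the union of all k-cliques reachable from one
another through "adjacent" k-cliques — cliques sharing k - 1 nodes. Unlike
partitioning methods, a node may belong to several communities; the overlap
count itself is informative (genes bridging dense modules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["CommunitySet", "maximal_cliques", "k_clique_communities", "overlap_report"]


@dataclass
class CommunitySet:
    """k-clique communities of a network, with overlap bookkeeping."""

    k: int
    communities: list[tuple]
    overlap_nodes: dict = field(default_factory=dict)
    covered: frozenset = frozenset()

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def n_covered(self) -> int:
        return len(self.covered)


def maximal_cliques(G: nx.Graph) -> list[tuple]:
    """All maximal cliques (Bron-Kerbosch), as sorted tuples in
    deterministic order (size descending, then lexicographic)."""
    cliques = [tuple(sorted(c, key=str)) for c in nx.find_cliques(G)]
    return sorted(cliques, key=lambda c: (-len(c), tuple(map(str, c))))


def k_clique_communities(G: nx.Graph, k: int = 3) -> CommunitySet:
    """Communities as percolation clusters of k-cliques.

    Two k-cliques are adjacent when they share k - 1 nodes; a community is
    the union of the cliques of one percolation cluster. Communities are
    returned as sorted node tuples, largest first; ``overlap_nodes`` maps
    each node in >= 2 communities to its community count.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    comms = [
        tuple(sorted(c, key=str))
        for c in nx.community.k_clique_communities(G, k)
    ]
    comms.sort(key=lambda c: (-len(c), tuple(map(str, c))))
    counts: dict = {}
    for comm in comms:
        for v in comm:
            counts[v] = counts.get(v, 0) + 1
    covered = frozenset(counts)
    overlap = {v: c for v, c in counts.items() if c >= 2}
    return CommunitySet(k=k, communities=comms, overlap_nodes=overlap, covered=covered)


def overlap_report(cs: CommunitySet) -> list[tuple]:
    """Nodes belonging to two or more communities, sorted by community count
    descending, then lexicographically."""
    return sorted(cs.overlap_nodes.items(), key=lambda p: (-p[1], str(p[0])))
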