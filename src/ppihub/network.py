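"""Assembly and curation of gene-level protein-protein interaction networks.

Interaction records from heterogeneous sources (edge-list TSV, SIF) are
canonicalized to uppercase gene symbols, optionally mapped through an
isoform/alias table, deduplicated, and stored in a simple undirected graph.
Edge provenance (which input file contributed an interaction) is kept as a
set of source tags per edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "PPINetwork",
    "CoverageReport",
    "canonical_symbol",
    "load_isoform_map",
    "parse_interactions",
    "build_network",
    "seed_coverage",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One raw pairwise interaction, before curation."""

    a: str
    b: str
    source: str = ""


@dataclass(frozen=True)
class CoverageReport:
    """How much of a seed gene list is present in the network."""

    n_seeds: int
    n_present: int
    fraction: float
    missing: frozenset[str]


class PPINetwork(nx.Graph):
    """Simple undirected gene-level interaction graph.

    Nodes are canonical (uppercase) gene symbols; the ``sources`` edge
    attribute records the set of input tags that reported the interaction.
    No self-loops, no parallel edges.
    """

    def edge_sources(self, a: str, b: str) -> frozenset[str]:
        return frozenset(self.edges[a, b].get("sources", ()))


def canonical_symbol(raw: str, isoform_map: Mapping[str, str] | None = None) -> str:
    """Map a raw identifier through the isoform table, then uppercase.

    Unmapped identifiers pass through unchanged (curation of real interaction
    indexes is never complete); idempotent on canonical symbols.
    """
    token = raw.strip()
    if isoform_map:
        token = isoform_map.get(token, isoform_map.get(token.upper(), token))
    return token.upper()


def load_isoform_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping raw identifier -> gene symbol."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1].upper()
    return mapping


def parse_interactions(
    path: str | Path,
    format: str = "edgelist",
    columns: tuple[int, int] = (0, 1),
) -> list[InteractionRecord]:
    """Parse an interaction file into raw records, one per data line.

    ``edgelist``: whitespace/tab separated, gene pair in ``columns`` (default
    first two; set e.g. ``columns=(0, 1)`` on a PSI-MITAB-like export to pull
    the two identifier columns). ``sif``: ``A <relation> B [C ...]``; a
    two-column line is accepted as a bare pair. Lines starting with ``#`` are
    skipped. Malformed lines raise with their line number.
    """
    if format not in {"edgelist", "sif"}:
        raise ValueError(f"unknown interaction format: {format!r}")
    path = Path(path)
    source = path.name
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if format == "edgelist":
                ca, cb = columns
                if len(parts) <= max(ca, cb):
                    raise ValueError(
                        f"{path}: line {lineno}: expected at least "
                        f"{max(ca, cb) + 1} columns, got {len(parts)}"
                    )
                records.append(InteractionRecord(parts[ca], parts[cb], source))
            else:  # sif
                if len(parts) == 1:
                    continue  # isolated-node line, legal SIF, carries no edge
                if len(parts) == 2:
                    records.append(InteractionRecord(parts[0], parts[1], source))
                else:
                    a = parts[0]
                    for b in parts[2:]:
                        records.append(InteractionRecord(a, b, source))
    if not records:
        logger.warning("no interaction records parsed from %s", path)
    return records


def build_network(
    records: Iterable[InteractionRecord],
    isoform_map: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Curate raw records into a simple undirected gene-level graph.

    Identifiers are canonicalized (isoform map, then uppercase), duplicate
    edges collapse with their source tags unioned, and self-interactions are
    dropped: every downstream centrality index assumes a simple graph.
    """
    net = PPINetwork()
    unmapped: set[str] = set()
    for rec in records:
        if isoform_map is not None:
            for raw in (rec.a, rec.b):
                if raw.strip() not in isoform_map and raw.strip().upper() not in isoform_map:
                    unmapped.add(raw.strip())
        a = canonical_symbol(rec.a, isoform_map)
        b = canonical_symbol(rec.b, isoform_map)
        if not a or not b:
            continue
        if a == b:
            continue  # self-loop
        if net.has_edge(a, b):
            net.edges[a, b]["sources"].add(rec.source)
        else:
            net.add_edge(a, b, sources={rec.source})
    if isoform_map and unmapped:
        logger.warning(
            "%d identifiers not in isoform map, passed through: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    return net


def seed_coverage(network: nx.Graph, seeds: Iterable[str]) -> CoverageReport:
    """Report how many seed genes the network covers.

    Mirrors the curation bookkeeping of cross-referencing a candidate gene
    list against an interaction index: genes without any known interaction
    fall out of the network.
    """
    seed_set = {canonical_symbol(s) for s in seeds}
    seed_set.discard("")
    if not seed_set:
        raise ValueError("seed set is empty")
    present = seed_set & set(network.nodes)
    return CoverageReport(
        n_seeds=len(seed_set),
        n_present=len(present),
        fraction=len(present) / len(seed_set),
        missing=frozenset(seed_set - present),
    )


def _sorted_edges(network: nx.Graph):
    """Edges as (u, v) with u <= v by label, in deterministic order."""
    ordered = (
        (u, v) if str(u) <= str(v) else (v, u) for u, v in network.edges
    )
    return sorted(ordered, key=lambda e: (str(e[0]), str(e[1])))


def export_network(network: nx.Graph, path: str | Path, format: str = "sif") -> Path:
    """Write the network to ``sif``, ``graphml`` or ``edgelist``.

    Round-trip safe: re-reading the file reproduces node and edge sets.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in _sorted_edges(network):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(nx.isolates(network), key=str):
                fh.write(f"{n}\n")
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("#gene_a\tgene_b\tsource\n")
            for u, v in _sorted_edges(network):
                srcs = ";".join(sorted(network.edges[u, v].get("sources", ())))
                fh.write(f"{u}\t{v}\t{srcs}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in network.nodes)
        for u, v in network.edges:
            srcs = ";".join(sorted(network.edges[u, v].get("sources", ())))
            g.add_edge(str(u), str(v), sources=srcs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return path


def read_network(path: str | Path, format: str = "edgelist") -> PPINetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if format in {"edgelist", "sif"}:
        net = build_network(parse_interactions(path, format=format))
        if format == "sif":  # re-attach isolated nodes (single-column lines)
            with open(path) as fh:
                for line in fh:
                    parts = line.split()
                    if len(parts) == 1:
                        net.add_node(canonical_symbol(parts[0]))
        return net
    if format == "graphml":
        g = nx.read_graphml(path)
        net = PPINetwork()
        net.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            srcs = set(filter(None, str(data.get("sources", "")).split(";")))
            net.add_edge(u, v, sources=srcs)
        return net
    raise ValueError(f"unknown network format: {format!r}")
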