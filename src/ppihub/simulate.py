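"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all bit-reproducible under a fixed seed and all emitting a
machine-readable ground-truth record alongside the data:

* an interaction network with a preferential-attachment (Barabasi-Albert)
  backbone — whose degree distribution is scale-free, matching the power-law
  behavior typical of curated PPI networks — plus optional planted hubs
  (nodes wired to a stated fraction of the network) and planted cliques
  (dense modules for community recovery);
* GMT gene-set collections with one planted over-represented set in a
  designated query;
* two-group expression matrices with multiplicative log-normal noise and a
  block of spiked genes at a stated true fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .deg import ExpressionMatrix
from .network import PPINetwork

__all__ = [
    "SyntheticNetworkConfig",
    "SyntheticExpressionConfig",
    "generate_network",
    "generate_gene_sets",
    "generate_expression",
    "write_ground_truth",
    "write_expression",
]


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    """Backbone plus planted-structure parameters for network generation."""

    n_nodes: int = 500
    attachment_m: int = 2
    backbone: str = "ba"  # "ba" (preferential attachment) or "er" (Erdos-Renyi)
    er_p: float = 0.01
    n_planted_hubs: int = 0
    hub_wiring_fraction: float = 0.2
    n_planted_cliques: int = 0
    clique_size: int = 6
    cliques_on_fresh_nodes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in {"ba", "er"}:
            raise ValueError(f"unknown backbone: {self.backbone!r}")
        if self.backbone == "ba" and not self.n_nodes > self.attachment_m >= 1:
            raise ValueError("need n_nodes > attachment_m >= 1")
        if self.n_planted_cliques and self.clique_size < 3:
            raise ValueError("clique_size must be >= 3")
        if self.n_planted_cliques * self.clique_size > self.n_nodes:
            raise ValueError("planted cliques do not fit in the network")


@dataclass(frozen=True)
class SyntheticExpressionConfig:
    """Design of a two-group expression experiment with spiked genes."""

    n_genes: int = 200
    n_case: int = 10
    n_control: int = 10
    n_de: int = 10
    true_fc: float = 4.0
    noise_cv: float = 0.1
    baseline_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de must be <= n_genes")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.true_fc < 1:
            raise ValueError("true_fc must be >= 1")


def _gene_label(i: int) -> str:
    return f"G{i:05d}"


def generate_network(config: SyntheticNetworkConfig) -> tuple[PPINetwork, dict]:
    """Generate a synthetic PPI network and its ground truth.

    The backbone is Barabasi-Albert (m isolated seed nodes, each new node
    attaching m edges preferentially, so the edge count is m*(n - m)) or
    sparse Erdos-Renyi. Planted hubs are fresh nodes wired to
    ``hub_wiring_fraction`` of uniformly chosen backbone nodes; planted
    cliques are made pairwise adjacent on vertex-disjoint node samples
    (or fresh nodes). Ground truth records hub ids and clique memberships.
    """
    rng = np.random.default_rng(config.seed)
    if config.backbone == "ba":
        g = nx.barabasi_albert_graph(
            config.n_nodes, config.attachment_m, seed=int(rng.integers(2**31 - 1))
        )
    else:
        g = nx.fast_gnp_random_graph(
            config.n_nodes, config.er_p, seed=int(rng.integers(2**31 - 1))
        )
    net = PPINetwork()
    backbone_nodes = [_gene_label(i) for i in range(config.n_nodes)]
    net.add_nodes_from(backbone_nodes)
    for u, v in g.edges:
        net.add_edge(_gene_label(u), _gene_label(v), sources={"backbone"})

    # planted nodes first continue the backbone label sequence; at the end
    # all labels are permuted so that a node's name carries no information
    # about its role (and no systematic lexicographic rank, which would bias
    # label-tie-breaking indexes for or against planted structure)
    fresh = config.n_nodes
    hubs = []
    for _ in range(config.n_planted_hubs):
        hub = _gene_label(fresh)
        fresh += 1
        n_links = max(1, round(config.hub_wiring_fraction * config.n_nodes))
        targets = rng.choice(config.n_nodes, size=n_links, replace=False)
        for t in targets:
            net.add_edge(hub, _gene_label(int(t)), sources={"planted_hub"})
        hubs.append(hub)

    cliques: list[list[str]] = []
    if config.n_planted_cliques:
        if config.cliques_on_fresh_nodes:
            pool = []
            for _ in range(config.n_planted_cliques * config.clique_size):
                pool.append(_gene_label(fresh))
                fresh += 1
        else:
            chosen = rng.choice(
                config.n_nodes,
                size=config.n_planted_cliques * config.clique_size,
                replace=False,
            )
            pool = [_gene_label(int(i)) for i in chosen]
        for c in range(config.n_planted_cliques):
            members = pool[c * config.clique_size:(c + 1) * config.clique_size]
            for i, u in enumerate(members):
                for v in members[i + 1:]:
                    if net.has_edge(u, v):
                        net.edges[u, v]["sources"].add("planted_clique")
                    else:
                        net.add_edge(u, v, sources={"planted_clique"})
            cliques.append(sorted(members))

    # exchangeable labels: uniform random permutation over all nodes
    ordered = sorted(net.nodes)
    shuffled = [ordered[i] for i in rng.permutation(len(ordered))]
    relabel = dict(zip(ordered, shuffled))
    relabeled = PPINetwork()
    relabeled.add_nodes_from(relabel[v] for v in net.nodes)
    for u, v, data in net.edges(data=True):
        relabeled.add_edge(relabel[u], relabel[v], **data)
    net = relabeled
    hubs = [relabel[h] for h in hubs]
    cliques = [sorted(relabel[v] for v in members) for members in cliques]

    truth = {
        "hubs": hubs,
        "cliques": cliques,
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "config": {
            "backbone": config.backbone,
            "n_nodes": config.n_nodes,
            "attachment_m": config.attachment_m,
            "seed": config.seed,
        },
    }
    return net, truth


def generate_gene_sets(
    universe,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    query_size: int = 40,
    enriched_fraction: float = 0.8,
    n_classes: int = 0,
    seed: int = 0,
) -> tuple[GeneSetCollection, list, dict]:
    """Random gene-set collection with one planted over-represented set.

    Sets are uniform samples from the universe; the designated query draws
    ``enriched_fraction`` of its genes from the target set (the first set)
    and the rest uniformly from the remaining universe. With
    ``enriched_fraction`` equal to the base rate the construction is null.
    Optional class labels are assigned cyclically over ``n_classes`` labels.
    """
    universe = sorted({str(g).upper() for g in universe})
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(universe)) or query_size > len(universe):
        raise ValueError("infeasible set or query sizes for this universe")
    rng = np.random.default_rng(seed)
    sets: dict = {}
    classes: dict = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"SET{i:03d}"
        sets[name] = {universe[j] for j in members}
        if n_classes:
            classes[name] = f"CLASS{i % n_classes}"
    target = "SET000"
    n_from_target = min(
        round(enriched_fraction * query_size), query_size, len(sets[target])
    )
    target_genes = sorted(sets[target])
    picked = list(
        rng.choice(len(target_genes), size=n_from_target, replace=False)
    )
    query = [target_genes[j] for j in picked]
    rest_pool = sorted(set(universe) - set(query))
    n_rest = query_size - len(query)
    if n_rest:
        extra = rng.choice(len(rest_pool), size=n_rest, replace=False)
        query += [rest_pool[j] for j in extra]
    truth = {"enriched_set": target, "query_size": query_size,
             "enriched_fraction": enriched_fraction}
    return GeneSetCollection(sets=sets, classes=classes), sorted(query), truth


def generate_expression(
    config: SyntheticExpressionConfig,
) -> tuple[ExpressionMatrix, dict]:
    """Two-group expression matrix with spiked fold changes.

    Per-gene baselines are log-normal around ``baseline_mean``; the first
    ``n_de`` genes have their case-group mean multiplied by ``true_fc``.
    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied so that the sample means are unbiased for the
    group means.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"GENE{i:05d}" for i in range(n)]
    baselines = config.baseline_mean * rng.lognormal(0.0, 0.5, size=n)
    case_means = baselines.copy()
    case_means[: config.n_de] *= config.true_fc
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    def _noise(shape):
        # mean-one multiplicative log-normal noise
        return rng.lognormal(-sigma**2 / 2.0, sigma, size=shape)

    case = case_means[:, None] * _noise((n, config.n_case))
    ctrl = baselines[:, None] * _noise((n, config.n_control))
    samples = [f"CASE{i:02d}" for i in range(config.n_case)] + [
        f"CTRL{i:02d}" for i in range(config.n_control)
    ]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    truth = {"de_genes": genes[: config.n_de], "true_fc": config.true_fc}
    return ExpressionMatrix(values=values, groups=groups), truth


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path


def write_expression(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    with open(groups_path, "w") as fh:
        for s in matrix.values.columns:
            fh.write(f"{s}\t{matrix.groups[s]}\n")
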