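"""End-to-end orchestration: expression prefilter -> seed genes -> network ->
centrality ensemble -> composite score -> communities -> model-based
clustering -> enrichment.

Every stage writes its outputs (TSV/JSON) before the next starts, and a run
manifest records the headline counts of each stage. A single master seed
derives the per-stage seeds by fixed offsets, so any stage can be rerun in
isolation with the same randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import centrality, clustering, communities, deg, enrichment, network, scoring

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_SEED_OFFSETS"]

#: Per-stage seed = (master_seed + offset) mod 2**31.
STAGE_SEED_OFFSETS = {"deg": 101, "epc": 202, "clustering": 303}


@dataclass
class PipelineConfig:
    """All inputs and knobs of a pipeline run (YAML-loadable)."""

    interaction_files: list = field(default_factory=list)
    interaction_format: str = "edgelist"
    isoform_map: str | None = None
    expression: list = field(default_factory=list)  # [{matrix, groups}, ...]
    extra_gene_lists: list = field(default_factory=list)
    top_k_per_list: int = 20
    seed_genes: str | None = None  # precomputed seed list, bypasses DEG merge
    gmt: str | None = None
    output_dir: str = "ppihub_out"
    master_seed: int = 0
    # stage parameters (defaults = the standard analysis settings)
    deg_alpha: float = 0.05
    deg_fc_threshold: float = 2.0
    deg_iterations: int | None = None
    deg_method: str = "permutation"
    epc_iterations: int = 1000
    epc_retain_probability: float = 0.5
    cpm_k: int = 3
    top_k: int = 50
    cluster_g_range: list = field(default_factory=lambda: list(range(1, 13)))
    cluster_models: list = field(default_factory=lambda: list(clustering.COVARIANCE_MODELS))
    enrichment_method: str = "ease"
    universe_mode: str = "annotated"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return (and write) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "master_seed": config.master_seed}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- differential expression prefilter + seed list -------------------
    seeds: set[str] = set()
    if config.seed_genes:
        stage("seeds")
        path = Path(config.seed_genes)
        seeds = {
            ln.strip().upper()
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        }
        manifest["n_seed_genes"] = len(seeds)
    elif config.expression or config.extra_gene_lists:
        stage("deg")
        union_result = None
        deg_counts = []
        for i, item in enumerate(config.expression):
            matrix = deg.load_expression(item["matrix"], item["groups"])
            result = deg.select_degs(
                matrix,
                alpha=config.deg_alpha,
                fc_threshold=config.deg_fc_threshold,
                B=config.deg_iterations,
                seed=config.stage_seed("deg") + i,
                method=config.deg_method,
            )
            _write_tsv(result.table, out / f"deg_{i}.tsv")
            deg_counts.append(
                {
                    "raw_significant": result.raw_significant,
                    "adjusted_significant": result.adjusted_significant,
                    "selected": len(result.selected_genes),
                }
            )
            if union_result is None:
                union_result = result
                union_selected = set(result.selected_genes)
            else:
                union_selected |= set(result.selected_genes)
        manifest["deg"] = deg_counts
        provenance = deg.merge_gene_lists(
            union_result, config.extra_gene_lists, config.top_k_per_list
        )
        if union_result is not None:
            for g in union_selected:
                provenance.setdefault(g, set()).add("deg")
        seeds = set(provenance)
        with open(out / "seed_genes.tsv", "w") as fh:
            for g in sorted(seeds):
                fh.write(f"{g}\t{';'.join(sorted(provenance[g]))}\n")
        manifest["n_seed_genes"] = len(seeds)

    # ---- network assembly -------------------------------------------------
    stage("network")
    if not config.interaction_files:
        raise ValueError("stage network: no interaction files configured")
    records = []
    for path in config.interaction_files:
        records.extend(
            network.parse_interactions(path, format=config.interaction_format)
        )
    isomap = network.load_isoform_map(config.isoform_map) if config.isoform_map else None
    net = network.build_network(records, isomap)
    network.export_network(net, out / "network.tsv", format="edgelist")
    manifest["n_nodes"] = net.number_of_nodes()
    manifest["n_edges"] = net.number_of_edges()
    if seeds:
        cov = network.seed_coverage(net, seeds)
        manifest["seed_coverage"] = {
            "n_seeds": cov.n_seeds,
            "n_present": cov.n_present,
            "fraction": cov.fraction,
        }

    # ---- centrality ensemble + composite score ----------------------------
    stage("centrality")
    epc_config = centrality.EpcConfig(
        n_iterations=config.epc_iterations,
        retain_probability=config.epc_retain_probability,
        seed=config.stage_seed("epc"),
    )
    table = centrality.compute_all_centralities(net, epc_config)
    _write_tsv(table, out / "centrality.tsv")

    stage("score")
    scores = scoring.score_i(table)
    _write_tsv(scores, out / "scores.tsv")
    restrict = sorted(seeds) if seeds else None
    top = scoring.top_genes(scores, config.top_k, restrict_to=restrict)
    with open(out / "top_genes.tsv", "w") as fh:
        fh.write("gene\tscore_i\n")
        for gene, s in top:
            fh.write(f"{gene}\t{s:.4f}\n")
    manifest["top_gene"] = top[0][0] if top else None

    # ---- communities -------------------------------------------------------
    stage("communities")
    cs = communities.k_clique_communities(net, k=config.cpm_k)
    with open(out / "communities.tsv", "w") as fh:
        fh.write("community_id\tsize\tmembers\n")
        for i, comm in enumerate(cs.communities, 1):
            fh.write(f"M{i}\t{len(comm)}\t{','.join(map(str, comm))}\n")
    with open(out / "community_overlap.tsv", "w") as fh:
        fh.write("node\tn_communities\n")
        for node, count in communities.overlap_report(cs):
            fh.write(f"{node}\t{count}\n")
    manifest["n_communities"] = cs.n_communities
    manifest["n_community_genes"] = cs.n_covered

    # ---- model-based clustering -------------------------------------------
    stage("clustering")
    features = scores.drop(columns=[scoring.SCORE_COLUMN])
    fit, bic_table = clustering.select_model(
        features,
        G_range=config.cluster_g_range,
        models=config.cluster_models,
        seed=config.stage_seed("clustering"),
    )
    _write_tsv(bic_table.set_index("G"), out / "bic_table.tsv")
    summary = clustering.summarize_clusters(fit, scores)
    summary_out = summary.copy()
    summary_out["members"] = summary_out["members"].map(lambda ms: ",".join(map(str, ms)))
    _write_tsv(summary_out, out / "cluster_summary.tsv")
    with open(out / "cluster_assignments.tsv", "w") as fh:
        fh.write("node\tcomponent\n")
        for node in sorted(fit.assignments, key=str):
            fh.write(f"{node}\t{fit.assignments[node]}\n")
    manifest["clustering"] = {
        "selected_G": fit.n_components,
        "covariance_model": fit.covariance_model,
        "bic": fit.bic,
    }

    # ---- enrichment ---------------------------------------------------------
    if config.gmt:
        stage("enrichment")
        gmt_path = Path(config.gmt)
        if not gmt_path.exists():
            raise ValueError(f"stage enrichment: GMT file not found: {gmt_path}")
        collection = enrichment.parse_gmt(gmt_path)
        universe = {str(n) for n in net.nodes}
        query = {g for g in (seeds or universe) if g in universe}
        result = enrichment.enrich(
            query,
            collection,
            universe,
            method=config.enrichment_method,
            universe_mode=config.universe_mode,
        )
        _write_tsv(result.table.set_index("name"), out / "enrichment_sets.tsv")
        _write_tsv(result.class_table.set_index("name"), out / "enrichment_classes.tsv")
        manifest["enrichment"] = {
            "coverage": result.coverage,
            "n_enriched_sets_adj05": int((result.table["adjusted_p"] <= 0.05).sum())
            if len(result.table)
            else 0,
        }

    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
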