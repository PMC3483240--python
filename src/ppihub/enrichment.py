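"""Gene-set over-representation analysis (pathways, diseases, GO-style sets).

Given a query gene list and a GMT collection, each set is scored by the
hypergeometric upper tail P(X >= k) for the observed overlap k, or by the
more conservative EASE variant (the same tail recomputed with the overlap
reduced by one, the default of the DAVID service this replaces). Set-level
p-values are corrected by Benjamini-Hochberg. Sets carrying a class label in
the GMT description column (e.g. disease classes such as "Cancer" or
"Cardiovascular") are additionally aggregated into class-level rows, the
class gene set being the union of its member sets.

The default test universe is the annotated universe — genes of the supplied
background that appear in at least one set — since un-annotated genes can
never contribute to an overlap; the full background is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "parse_gmt",
    "write_gmt",
    "set_pvalue",
    "bh_adjust",
    "enrich",
]

UNCLASSIFIED = "unclassified"


@dataclass
class GeneSetCollection:
    """Named gene sets with optional class labels (GMT-backed)."""

    sets: dict = field(default_factory=dict)
    classes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def annotated_genes(self) -> set:
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return out

    def class_sets(self) -> dict:
        """Union of member sets per class label (sets without a label are
        grouped under 'unclassified')."""
        out: dict = {}
        for name, genes in self.sets.items():
            label = self.classes.get(name, UNCLASSIFIED)
            out.setdefault(label, set()).update(genes)
        return out


@dataclass
class EnrichmentResult:
    """Set- and class-level over-representation table plus coverage."""

    table: pd.DataFrame
    class_table: pd.DataFrame
    coverage: float
    universe_size: int
    query_size: int


def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name <TAB> description <TAB> gene ...`` per line.

    A non-empty description other than '.'/'na'/'NA' is taken as the set's
    class label. Duplicate set names raise; lines with no genes are skipped
    with a warning.
    """
    sets: dict = {}
    classes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 tab-separated fields")
            name, desc = parts[0].strip(), parts[1].strip()
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not genes:
                logger.warning("%s: line %d: set %r has no genes, skipped", path, lineno, name)
                continue
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            if desc and desc.lower() not in {".", "na"}:
                classes[name] = desc
    return GeneSetCollection(sets=sets, classes=classes)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.classes.get(name, ".")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
    return path


def set_pvalue(k: int, n: int, K: int, N: int, method: str = "hypergeometric") -> float:
    """Upper-tail enrichment p-value for an overlap of k.

    k = overlap, n = query size, K = set size, N = universe size.
    ``hypergeometric``: P(X >= k). ``ease``: P(X >= k - 1) computed on the
    same margins — the one-gene penalty of the DAVID EASE score (k <= 1 gives
    p = 1).
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if method == "hypergeometric":
        k_eff = k
    elif method == "ease":
        k_eff = k - 1
    else:
        raise ValueError(f"unknown method: {method!r}")
    if k_eff <= 0:
        return 1.0
    # sf(x) = P(X > x), so P(X >= k_eff) = sf(k_eff - 1)
    return float(hypergeom.sf(k_eff - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _score_sets(sets: dict, query: set, universe: set, method: str) -> pd.DataFrame:
    rows = []
    N, n = len(universe), len(query)
    for name in sorted(sets):
        members = sets[name] & universe
        overlap = query & members
        k, K = len(overlap), len(members)
        if k == 0 or K == 0:
            continue
        rows.append(
            {
                "name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": set_pvalue(k, n, K, N, method=method),
                "genes": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "genes"],
    )
    if len(df):
        df["adjusted_p"] = bh_adjust(df["p_value"])
        df = df.sort_values(["p_value", "name"], ignore_index=True)
    else:
        df["adjusted_p"] = []
    return df


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    method: str = "ease",
    universe_mode: str = "annotated",
) -> EnrichmentResult:
    """Over-representation of ``query`` against every set of the collection.

    ``universe`` is the background gene population (typically all network
    nodes); with ``universe_mode='annotated'`` (default) it is restricted to
    genes appearing in >= 1 set, and the query is restricted accordingly.
    Returns set-level and class-level tables (overlap >= 1 only, BH-adjusted
    within each table) plus the annotation coverage of the background.
    """
    universe = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in query}
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    annotated = collection.annotated_genes & universe
    coverage = len(annotated) / len(universe)
    if universe_mode == "annotated":
        eff_universe = annotated
    elif universe_mode == "all":
        eff_universe = universe
    else:
        raise ValueError(f"unknown universe_mode: {universe_mode!r}")
    eff_query = query & eff_universe
    if not eff_universe:
        table = _score_sets({}, set(), {"_"}, method)
        return EnrichmentResult(table, table.copy(), 0.0, 0, len(eff_query))
    table = _score_sets(collection.sets, eff_query, eff_universe, method)
    class_table = _score_sets(collection.class_sets(), eff_query, eff_universe, method)
    return EnrichmentResult(
        table=table,
        class_table=class_table,
        coverage=coverage,
        universe_size=len(eff_universe),
        query_size=len(eff_query),
    )
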