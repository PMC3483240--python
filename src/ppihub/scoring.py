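"""Composite hub score from an ensemble of centrality indexes.

Each centrality column is min-max normalized to a 0-100 percentage across
all network nodes, and the composite score of a node is the sum of its
normalized percentages over the Nc indexes:

    score(v) = sum_i 100 * (Ic_i(v) - min_i) / (max_i - min_i)

which is bounded by 100 * Nc (1000 for the standard 10-index ensemble).
Normalization is computed over the whole network; restriction to a seed
gene list happens only at ranking time, so a seed gene's score reflects its
standing among all nodes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["normalize_index", "score_i", "top_genes", "partition_top_genes"]

SCORE_COLUMN = "score_i"


def normalize_index(values: Mapping) -> dict:
    """Min-max normalize one index to percentages in [0, 100].

    The minimum maps to 0 and the maximum to 100; the map is order
    preserving. A constant column (max == min, where the definition divides
    by zero) contributes 0 for every node: an index that does not vary
    carries no ranking information.
    """
    if len(values) == 0:
        raise ValueError("cannot normalize an empty index")
    arr = np.asarray(list(values.values()), dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("index values must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: 100.0 * (v - lo) / (hi - lo) for k, v in values.items()}


def score_i(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize every centrality column and sum into the composite score.

    ``table`` is a node x index DataFrame (any Nc >= 1 columns). Returns a
    DataFrame with the normalized percentage columns plus a ``score_i``
    column in [0, 100 * Nc]. Invariant under column permutation and under
    strictly increasing affine rescaling of any single raw column.
    """
    if table.shape[1] < 1:
        raise ValueError("centrality table needs at least one index column")
    arr = table.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("centrality table contains non-finite values")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    normalized = np.zeros_like(arr)
    nz = span > 0
    normalized[:, nz] = 100.0 * (arr[:, nz] - lo[nz]) / span[nz]
    out = pd.DataFrame(normalized, index=table.index, columns=table.columns)
    out[SCORE_COLUMN] = normalized.sum(axis=1)
    return out


def _ranked(scores: pd.DataFrame) -> list[tuple[str, float]]:
    pairs = [(str(node), float(s)) for node, s in scores[SCORE_COLUMN].items()]
    # descending score, ascending symbol: deterministic under ties
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def top_genes(
    scores: pd.DataFrame,
    k: int,
    restrict_to: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """Top-k genes by composite score, optionally restricted to a seed list.

    Ties are broken lexicographically by gene symbol. If fewer than ``k``
    genes are available, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = _ranked(scores)
    if restrict_to is not None:
        allowed = {str(g).upper() for g in restrict_to}
        ranked = [p for p in ranked if p[0].upper() in allowed]
    return ranked[:k]


def partition_top_genes(
    scores: pd.DataFrame,
    k: int,
    restrict_to: Iterable[str],
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-k inside a seed list plus the top-k high scorers outside it.

    The second list surfaces genes that rank highly by network topology but
    were not part of the initial candidate set — often worth follow-up.
    """
    allowed = {str(g).upper() for g in restrict_to}
    ranked = _ranked(scores)
    inside = [p for p in ranked if p[0].upper() in allowed][:k]
    outside = [p for p in ranked if p[0].upper() not in allowed][:k]
    return inside, outside
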