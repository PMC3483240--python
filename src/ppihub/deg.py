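"""Two-group differential expression prefilter with resampling p-values.

For each gene of a case/control expression matrix (linear scale), the test
statistic is the difference of group means of log2 values; its significance
is assessed by label permutation (default) or by a null bootstrap of
group-mean differences. Raw p-values are Benjamini-Hochberg adjusted and a
gene is selected when adjusted p <= alpha AND its linear fold change is at
least ``fc_threshold`` in either direction (fold change is case mean over
control mean, applied symmetrically, so 2-fold down counts like 2-fold up).

The permutation p-value uses the add-one estimator
p = (1 + #{|T*| >= |T|}) / (B + 1), which is never exactly zero and is valid
for any B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "DEGResult",
    "load_expression",
    "resampling_pvalue",
    "select_degs",
    "merge_gene_lists",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (linear scale) with group labels."""

    values: pd.DataFrame  # index = genes, columns = sample ids
    groups: dict  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        labels = set(self.groups[s] for s in self.values.columns)
        if labels - {"case", "control"}:
            raise ValueError(f"unknown group labels: {labels - {'case', 'control'}}")
        if not {"case", "control"} <= labels:
            raise ValueError("both case and control samples are required")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression values must be positive (linear scale)")

    @property
    def case_samples(self) -> list:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list:
        return [s for s in self.values.columns if self.groups[s] == "control"]


@dataclass
class DEGResult:
    """Per-gene differential-expression statistics and selection flags."""

    table: pd.DataFrame  # gene, fold_change, raw_p, adjusted_p, selected
    alpha: float
    fc_threshold: float
    n_iterations: int
    raw_significant: int = 0
    adjusted_significant: int = 0

    @property
    def selected_genes(self) -> list:
        return sorted(self.table.index[self.table["selected"]], key=str)


def load_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Load a gene x sample TSV (first column = gene, header = sample ids)
    and a 2-column sample->group TSV (labels ``case``/``control``)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    groups: dict = {}
    with open(groups_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{groups_path}: line {lineno}: expected 2 columns")
            groups[parts[0]] = parts[1].lower()
    return ExpressionMatrix(values=values, groups=groups)


def _perm_stats(values: np.ndarray, n_case: int, B: int, rng) -> np.ndarray:
    """Null statistics from B random label permutations of one gene."""
    n = values.size
    order = np.argsort(rng.random((B, n)), axis=1)
    perm = values[order]
    return perm[:, :n_case].mean(axis=1) - perm[:, n_case:].mean(axis=1)


def _boot_stats(values: np.ndarray, n_case: int, B: int, rng) -> np.ndarray:
    """Null statistics by bootstrapping group-mean differences after
    centering both groups to the pooled mean."""
    centered = values - values.mean()
    case_idx = rng.integers(0, n_case, size=(B, n_case))
    ctrl_idx = rng.integers(n_case, values.size, size=(B, values.size - n_case))
    return centered[case_idx].mean(axis=1) - centered[ctrl_idx].mean(axis=1)


def resampling_pvalue(
    case: Sequence[float],
    control: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """Two-sided resampling p-value for a difference of log2 group means.

    Each group needs >= 2 samples and B >= 100. If every value is identical
    the statistic is degenerate and p = 1.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if B < 100:
        raise ValueError("B must be >= 100")
    if (case <= 0).any() or (control <= 0).any():
        raise ValueError("expression values must be positive")
    log_vals = np.log2(np.concatenate([case, control]))
    if np.ptp(log_vals) == 0:
        return 1.0
    t_obs = log_vals[: case.size].mean() - log_vals[case.size:].mean()
    rng = np.random.default_rng(seed)
    null_fn = {"permutation": _perm_stats, "bootstrap": _boot_stats}.get(method)
    if null_fn is None:
        raise ValueError(f"unknown method: {method!r}")
    t_null = null_fn(log_vals, case.size, B, rng)
    return float((1 + np.sum(np.abs(t_null) >= abs(t_obs))) / (B + 1))


def choose_iterations(n_samples: int) -> int:
    """Resampling depth heuristic: deeper null for larger designs."""
    return 10000 if n_samples >= 20 else 1000


def select_degs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    B: int | None = None,
    seed: int = 0,
    method: str = "permutation",
) -> DEGResult:
    """Differentially expressed genes: resampling p per gene, BH correction,
    symmetric fold-change filter.

    Reports both the raw-significant and (smaller) adjusted-significant gene
    counts — the two-stage reduction characteristic of FDR-corrected
    screens.
    """
    n_samples = matrix.values.shape[1]
    if B is None:
        B = choose_iterations(n_samples)
    cases = matrix.values[matrix.case_samples].to_numpy(dtype=float)
    ctrls = matrix.values[matrix.control_samples].to_numpy(dtype=float)
    genes = list(matrix.values.index)
    rng = np.random.default_rng(seed)
    raw_p = np.empty(len(genes))
    fc = np.empty(len(genes))
    for i in range(len(genes)):
        fc[i] = cases[i].mean() / ctrls[i].mean()
        raw_p[i] = resampling_pvalue(
            cases[i], ctrls[i], B=B,
            seed=int(rng.integers(0, 2**31 - 1)), method=method,
        )
    adj_p = np.asarray(bh_adjust(raw_p))
    sym_fc = np.maximum(fc, 1.0 / fc)
    selected = (adj_p <= alpha) & (sym_fc >= fc_threshold)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "raw_p": raw_p,
            "adjusted_p": adj_p,
            "selected": selected,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEGResult(
        table=table,
        alpha=alpha,
        fc_threshold=fc_threshold,
        n_iterations=B,
        raw_significant=int((raw_p <= alpha).sum()),
        adjusted_significant=int((adj_p <= alpha).sum()),
    )


def merge_gene_lists(
    deg: DEGResult | None,
    extra_lists: Sequence[str | Path] = (),
    top_k_per_list: int = 20,
) -> dict:
    """Union selected DEGs with the head of each ranked external gene list.

    External lists (e.g. text-mining outputs) are one-symbol-per-line files,
    best-first; only the top ``top_k_per_list`` entries of each are taken.
    Returns gene -> set of provenance tags ('deg' or the list file name).
    """
    seeds: dict = {}
    if deg is not None:
        for g in deg.selected_genes:
            seeds.setdefault(str(g).upper(), set()).add("deg")
    for path in extra_lists:
        path = Path(path)
        try:
            lines = path.read_text().splitlines()
        except OSError as exc:
            raise ValueError(f"cannot read gene list {path}: {exc}") from exc
        head = [ln.strip().upper() for ln in lines if ln.strip() and not ln.startswith("#")]
        for g in head[:top_k_per_list]:
            seeds.setdefault(g, set()).add(path.name)
    return seeds
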