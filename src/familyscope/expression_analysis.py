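"""FPKM filtering, differential expression, and co-expression networks.

Differential expression between two sample groups uses a Welch t test on
log2(FPKM + 1) with a fold-change filter on the raw group means (pseudocount
1).  The fold-change threshold defaults to 2: a threshold of exactly 1
(any increase qualifies) is degenerate but available for compatibility
with laxer published criteria.  Co-expression edges between family genes
and hormone-pathway genes carry the Pearson coefficient over the six
flowering-stage means, a two-sided t-based p-value (df = n - 2), and the
correlation sign; "top 10 per gene" keeps the largest |r| so negative
regulators are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TabularMatrix

logger = logging.getLogger("familyscope")


@dataclass
class DegCall:
    gene_id: str
    comparison: tuple[str, str]  # (group_a, group_b)
    fold_change: float  # (mean_b + 1) / (mean_a + 1)
    p_value: float
    direction: str  # up | down


@dataclass
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float
    p_value: float
    n: int

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


def _group_columns(matrix: TabularMatrix) -> dict[str, list[str]]:
    if not matrix.col_groups:
        raise ValueError("expression matrix carries no column group labels")
    groups: dict[str, list[str]] = {}
    for col in matrix.col_ids:
        groups.setdefault(matrix.col_groups[col], []).append(col)
    return groups


def group_means(matrix: TabularMatrix) -> pd.DataFrame:
    """Per-group mean FPKM (genes x groups, groups in first-seen order)."""
    cols = _group_columns(matrix)
    return pd.DataFrame(
        {group: matrix.values[cs].mean(axis=1) for group, cs in cols.items()}
    )


def filter_expressed(matrix: TabularMatrix, min_fpkm: float = 1.0) -> list[str]:
    """Genes whose maximum group-mean FPKM exceeds ``min_fpkm``."""
    means = group_means(matrix)
    kept = list(means.index[means.max(axis=1) > min_fpkm])
    logger.info("filter_expressed: %d of %d genes above FPKM %g",
                len(kept), len(means), min_fpkm)
    return kept


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_degs(
    matrix: TabularMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    bh_correct: bool = False,
) -> list[DegCall]:
    """Differentially expressed genes between two groups.

    Welch t test on log2(FPKM + 1); a gene is a DEG iff p < ``p_threshold``
    and the fold change (on raw means, pseudocount 1) is >= ``fc_threshold``
    or <= 1/``fc_threshold``.  Benjamini-Hochberg adjustment is off by
    default (raw-p criterion) and available via ``bh_correct``.
    """
    cols = _group_columns(matrix)
    for group in (group_a, group_b):
        if group not in cols:
            raise ValueError(f"group {group!r} absent from the matrix")
    raw_a = matrix.values[cols[group_a]].to_numpy(float)
    raw_b = matrix.values[cols[group_b]].to_numpy(float)
    log_a = np.log2(raw_a + 1.0)
    log_b = np.log2(raw_b + 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvals = np.asarray(t_res.pvalue, dtype=float)
    # zero variance in both groups: p = 1 when means agree, ~0 otherwise
    degenerate = np.isnan(pvals)
    if degenerate.any():
        equal = np.isclose(log_b.mean(axis=1), log_a.mean(axis=1))
        pvals[degenerate & equal] = 1.0
        pvals[degenerate & ~equal] = 0.0
    if bh_correct:
        pvals = _bh_adjust(pvals)

    fc = (raw_b.mean(axis=1) + 1.0) / (raw_a.mean(axis=1) + 1.0)
    calls: list[DegCall] = []
    for gene, p, f in zip(matrix.row_ids, pvals, fc):
        if p >= p_threshold:
            continue
        if not (f >= fc_threshold or f <= 1.0 / fc_threshold):
            continue
        calls.append(
            DegCall(
                gene_id=gene,
                comparison=(group_a, group_b),
                fold_change=float(f),
                p_value=float(p),
                direction="up" if f > 1.0 else "down",
            )
        )
    logger.info("call_degs %s vs %s: %d DEGs of %d genes",
                group_a, group_b, len(calls), len(matrix.row_ids))
    return calls


def heatmap_matrix(matrix: TabularMatrix, genes: list[str] | None = None) -> TabularMatrix:
    """log2(FPKM + 1) group means, z-scored per gene across the stages.

    Constant genes become all-zero rows.
    """
    means = np.log2(group_means(matrix) + 1.0)
    if genes is not None:
        means = means.loc[genes]
    centered = means.sub(means.mean(axis=1), axis=0)
    sd = means.std(axis=1, ddof=0)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return TabularMatrix.from_frame(z, {c: c for c in z.columns})


def screen_pathway_genes(
    annotations: dict[str, set[str] | list[str]],
    pathway_domain_ids: list[str] | set[str],
) -> list[str]:
    """Genes whose domain annotation matches any configured Pfam-style id."""
    wanted = set(pathway_domain_ids)
    if not wanted:
        return []
    return sorted(
        {gene for gene, doms in annotations.items() if wanted & set(doms)}
    )


def coexpression_network(
    matrix: TabularMatrix,
    family_genes: list[str],
    pathway_genes: list[str],
    p_max: float = 0.05,
    top_k: int = 10,
    use_group_means: bool = True,
) -> list[CoexpressionEdge]:
    """Family x pathway Pearson co-expression edges.

    Correlations run over the stage means (or raw replicate columns when
    ``use_group_means`` is False); pairs with p >= ``p_max`` are deleted,
    then each gene keeps its ``top_k`` edges by |r| (union over endpoints).
    Edges are deduplicated under a canonical (sorted) gene ordering.
    """
    data = group_means(matrix) if use_group_means else matrix.values
    n = data.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for the correlation test")
    candidates: dict[tuple[str, str], CoexpressionEdge] = {}
    for fam in family_genes:
        for path in pathway_genes:
            if fam == path:
                continue
            key = tuple(sorted((fam, path)))
            if key in candidates:
                continue
            x = data.loc[fam].to_numpy(float)
            y = data.loc[path].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant expression vector; skipping pair {key}"
                )
                continue
            r, p = stats.pearsonr(x, y)
            if p >= p_max:
                continue
            candidates[key] = CoexpressionEdge(key[0], key[1], float(r), float(p), n)

    # per-gene top-k by |r|, kept if selected by either endpoint
    by_gene: dict[str, list[CoexpressionEdge]] = {}
    for edge in candidates.values():
        by_gene.setdefault(edge.gene_a, []).append(edge)
        by_gene.setdefault(edge.gene_b, []).append(edge)
    keep: set[tuple[str, str]] = set()
    for gene, edges in by_gene.items():
        edges.sort(key=lambda e: (-abs(e.r), e.gene_a, e.gene_b))
        for edge in edges[:top_k]:
            keep.add((edge.gene_a, edge.gene_b))
    result = sorted(
        (candidates[key] for key in keep), key=lambda e: (e.gene_a, e.gene_b)
    )
    logger.info("coexpression_network: %d edges kept of %d candidate pairs",
                len(result), len(candidates))
    return result
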