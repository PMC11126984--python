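"""Tag co-expression, group differential expression and LLPS enrichment.

These stages run on the log-normalized expression layer. Tag correlation
computes, per gene, the Pearson correlation with an exogenous tag's
(Dendra2/HaloTag) normalized expression over the analysis cells, a two-sided
p value from the t transform, and Benjamini-Hochberg adjusted q values.
Differential expression between two cell groups uses the two-sided Wilcoxon
rank-sum test with a p floor of 2.225074e-308 (the smallest normal double)
before Bonferroni adjustment, combined with a |log2 fold change| >= 0.5
threshold on de-logged group means. Gene-set enrichment of a significant set
against an LLPS membership list uses Fisher's exact test on the 2x2 table,
Bonferroni-corrected across the tested contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_qc import CountMatrix, NormalizedMatrix

__all__ = [
    "select_tag_positive_cells",
    "tag_correlation",
    "differential_expression",
    "llps_enrichment",
    "EnrichmentResult",
    "P_FLOOR",
]

P_FLOOR = 2.225074e-308  # smallest positive normal double; keeps log-scale plots finite
FOLD_CHANGE_EPS = 1e-9
LOG2FC_THRESHOLD = 0.5
ALPHA = 0.05


def select_tag_positive_cells(matrix: CountMatrix, tag_genes) -> np.ndarray:
    """Boolean cell mask: raw count > 0 for at least one tag gene."""
    tag_genes = list(tag_genes)
    if not tag_genes:
        raise ValueError("no tag genes given")
    rows = [matrix.gene_index(t) for t in tag_genes]  # KeyError names missing tag
    sub = matrix.counts[rows, :]
    return np.asarray((sub > 0).sum(axis=0)).ravel() > 0


def tag_correlation(
    normalized: NormalizedMatrix,
    tag_gene: str,
    alpha: float = ALPHA,
    cells: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a tag's normalized expression.

    Genes with no expression in any analysis cell are removed first;
    remaining zero-variance genes are dropped with a recorded reason.
    Returns a table (gene, r, p, q, significant, dropped_reason) where q is
    the Benjamini-Hochberg adjusted p and significant = (q < alpha). The tag
    gene itself is not tested against itself.
    """
    mask = np.ones(len(normalized.barcodes), dtype=bool) if cells is None else np.asarray(cells)
    vals = normalized.values[:, mask]
    tag_row = int(np.flatnonzero(normalized.gene_ids == tag_gene)[0]) if np.any(
        normalized.gene_ids == tag_gene
    ) else None
    if tag_row is None:
        raise KeyError(f"tag gene {tag_gene!r} not present")
    y = np.asarray(vals[tag_row].todense()).ravel()
    if np.all(y == y[0]):
        raise ValueError(f"tag {tag_gene!r} has zero variance in the analysis cells")
    n = y.size
    x = np.asarray(vals.todense())
    gene_ids = normalized.gene_ids
    keep = (x > 0).any(axis=1)
    keep[tag_row] = False
    dropped_allzero = gene_ids[~keep & (np.arange(len(gene_ids)) != tag_row)]
    x = x[keep]
    ids = gene_ids[keep]
    sd = x.std(axis=1)
    zero_var = sd == 0
    records = [
        {"gene": g, "r": np.nan, "p": np.nan, "q": np.nan,
         "significant": False, "dropped_reason": "zero variance"}
        for g in ids[zero_var]
    ]
    x = x[~zero_var]
    ids = ids[~zero_var]
    if len(ids):
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        r = (xc @ yc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc))
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
        q = multipletests(p, method="fdr_bh")[1]
        for g, ri, pi, qi in zip(ids, r, p, q):
            records.append(
                {"gene": g, "r": float(ri), "p": float(pi), "q": float(qi),
                 "significant": bool(qi < alpha), "dropped_reason": ""}
            )
    columns = ["gene", "r", "p", "q", "significant", "dropped_reason"]
    df = pd.DataFrame(records, columns=columns)
    df.attrs["removed_all_zero"] = list(dropped_allzero)
    df.attrs["tag"] = tag_gene
    df.attrs["n_cells"] = int(n)
    return df.sort_values("gene", kind="stable").reset_index(drop=True)


def differential_expression(
    normalized: NormalizedMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-group differential expression on the normalized layer.

    ``group_a``/``group_b`` are disjoint boolean cell masks or index arrays.
    Per gene: two-sided Wilcoxon rank-sum p (floored at 2.225074e-308 before
    adjustment), Bonferroni ``p_adj = min(1, m p)`` with m = genes tested,
    and ``log2fc = log2((mean_a(expm1 x) + eps) / (mean_b(expm1 x) + eps))``.
    Significant = (|log2fc| >= threshold) & (p_adj < alpha). Genes with no
    expression in either group's cells are not tested.
    """
    ia = _as_index(group_a, len(normalized.barcodes))
    ib = _as_index(group_b, len(normalized.barcodes))
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    xa = np.asarray(normalized.values[:, ia].todense())
    xb = np.asarray(normalized.values[:, ib].todense())
    expressed = (xa > 0).any(axis=1) | (xb > 0).any(axis=1)
    xa, xb = xa[expressed], xb[expressed]
    genes = normalized.gene_ids[expressed]
    m = len(genes)
    if m == 0:
        raise ValueError("no expressed genes in either group")
    res = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="asymptotic", axis=1)
    p = np.maximum(np.minimum(res.pvalue, 1.0), P_FLOOR)
    p_adj = np.minimum(1.0, m * p)
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2((mean_a + FOLD_CHANGE_EPS) / (mean_b + FOLD_CHANGE_EPS))
    significant = (np.abs(log2fc) >= log2fc_threshold) & (p_adj < alpha)
    df = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        }
    )
    df.attrs["n_a"] = int(ia.size)
    df.attrs["n_b"] = int(ib.size)
    df.attrs["m_tested"] = m
    return df.sort_values("gene", kind="stable").reset_index(drop=True)


def _as_index(group, n_cells: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if group.size != n_cells:
            raise ValueError("boolean group mask length mismatch")
        return np.flatnonzero(group)
    return group.astype(int)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher-exact enrichment of a gene set in an LLPS membership list."""

    table: np.ndarray  # [[sig&llps, sig&other], [notsig&llps, notsig&other]]
    odds_ratio: float
    p_value: float
    p_adjusted: float  # Bonferroni across n_contrasts
    n_significant: int
    n_llps: int
    n_universe: int


def llps_enrichment(
    significant_genes, llps_set, universe, n_contrasts: int = 1
) -> EnrichmentResult:
    """2x2 Fisher exact test of set membership among significant genes.

    ``llps_set`` is intersected with ``universe``; ``significant_genes`` must
    be a subset of the universe. The odds ratio is the sample OR, with a
    Haldane 0.5 correction when any cell is zero; an empty significant set
    yields p = 1 and an undefined (NaN) OR.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = set(significant_genes)
    if not sig <= universe:
        raise ValueError("significant genes must be a subset of the universe")
    llps = set(llps_set) & universe
    a = len(sig & llps)
    b = len(sig - llps)
    c = len(llps - sig)
    d = len(universe - sig - llps)
    table = np.array([[a, b], [c, d]])
    if not sig:
        p = 1.0
        odds = float("nan")
    else:
        _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=table,
        odds_ratio=float(odds),
        p_value=float(p),
        p_adjusted=float(min(1.0, n_contrasts * p)),
        n_significant=len(sig),
        n_llps=len(llps),
        n_universe=len(universe),
    )
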