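"""Correlation partitioning, pathway scoring and group comparisons.

Survival-significant bimodal genes are partitioned by the strength of their
Pearson correlation with a reference proliferation marker (MKI67 by
default): genes with |r| below the threshold are candidate biomarkers that
complement proliferation-based prognosis.  A pathway's activity per sample
is its unweighted mean log2(FPKM + 1) over the member genes; that score is
median-split and screened for survival exactly like a single gene.  The
default pathway set is the semaphorin-integrin signaling axis
(SEMA7A, ITGB1, AKT1, PTK2, MAPK1, LIMK1, CFL1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .survival import SurvivalResult, median_dichotomize, univariate_cox

__all__ = [
    "pearson_correlation",
    "partition_by_reference",
    "pathway_average_survival",
    "group_compare",
    "correlation_matrix",
    "DEFAULT_PATHWAY_GENES",
]

#: SEMA7A-integrin-beta1 downstream signaling axis, as gene symbols
#: (AKT -> AKT1, PTK/FAK -> PTK2, ERK -> MAPK1)
DEFAULT_PATHWAY_GENES = ("SEMA7A", "ITGB1", "AKT1", "PTK2", "MAPK1", "LIMK1", "CFL1")


def pearson_correlation(x, y) -> dict:
    """Pearson product-moment correlation with two-sided t-test p-value.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs with nonzero variance on both sides are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}


def partition_by_reference(
    significant_genes,
    matrix: pd.DataFrame,
    reference_gene: str = "MKI67",
    r_threshold: float = 0.3,
) -> dict:
    """Split genes by |Pearson r| against a reference gene.

    Returns ``{"low_correlated": [...], "high_correlated": [...],
    "correlations": DataFrame}``; a gene lands in ``low_correlated`` iff
    |r| < ``r_threshold``.  The full r table is always returned so any
    threshold can be audited.  The reference gene itself, if present in the
    input list, is high-correlated by construction (r = 1).
    """
    if reference_gene not in matrix.index:
        raise ValueError(f"reference gene {reference_gene!r} not in matrix")
    ref = matrix.loc[reference_gene].to_numpy(dtype=float)
    rows = []
    low, high = [], []
    for gene in significant_genes:
        if gene not in matrix.index:
            raise ValueError(f"gene {gene!r} not in matrix")
        res = pearson_correlation(matrix.loc[gene].to_numpy(dtype=float), ref)
        rows.append({"gene_id": gene, "r": res["r"], "p": res["p"], "n": res["n"]})
        (low if abs(res["r"]) < r_threshold else high).append(gene)
    return {
        "low_correlated": low,
        "high_correlated": high,
        "correlations": pd.DataFrame(rows, columns=["gene_id", "r", "p", "n"]),
    }


def pathway_average_survival(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_set=DEFAULT_PATHWAY_GENES,
) -> SurvivalResult:
    """Survival screen of the mean expression over a gene set.

    The per-sample score is the unweighted arithmetic mean of
    log2(FPKM + 1) over the member genes (no z-scoring); patients are
    median-split on the score and compared by log-rank + univariate Cox.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in matrix.index]
    if missing:
        raise ValueError(f"pathway genes absent from matrix: {missing}")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical else clinical
    score = matrix.loc[gene_set].mean(axis=0)
    clin = clin.loc[score.index]
    labels = median_dichotomize(score.to_numpy(dtype=float))
    res = univariate_cox(labels, clin["os_time"], clin["os_event"])
    res["feature_id"] = "+".join(gene_set)
    res["pathway_score"] = score
    return res


def group_compare(values, binary_labels, exact_max_n: int = 12):
    """Mann-Whitney U test of values between two groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and no ties straddle the groups, otherwise
    the tie-corrected normal approximation.  Returns ``(U, p)`` with U for
    the group labelled 1.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(binary_labels)
    a, b = v[lab == 1], v[lab == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n) else "asymptotic"
    if method == "exact" and np.unique(v).size < v.size:
        method = "asymptotic"  # exact null invalid under ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(matrix: pd.DataFrame, gene_set) -> pd.DataFrame:
    """All-pairs Pearson correlation table for a gene set.

    Returns a tidy frame (gene_a, gene_b, r, p, n) covering every ordered
    pair; the table is symmetric and the diagonal has r = 1, p = 0.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in matrix.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    rows = []
    for ga in gene_set:
        for gb in gene_set:
            if ga == gb:
                n = int(np.isfinite(matrix.loc[ga].to_numpy(dtype=float)).sum())
                rows.append({"gene_a": ga, "gene_b": gb, "r": 1.0, "p": 0.0, "n": n})
            else:
                res = pearson_correlation(
                    matrix.loc[ga].to_numpy(dtype=float),
                    matrix.loc[gb].to_numpy(dtype=float),
                )
                rows.append({"gene_a": ga, "gene_b": gb, **res})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "n"])
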