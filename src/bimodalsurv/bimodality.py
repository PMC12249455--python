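"""Per-gene bimodality screen: dip test, mixture fit, score, ranking.

The screen runs in two stages, mirroring the hybrid non-parametric /
parametric design of the method.  The dip test gatekeeps: only genes whose
expression distribution rejects unimodality (Monte-Carlo dip p-value below
``alpha_dip``) are fitted with the two-component normal mixture.  Fitted
genes get a bimodal score |mu1 - mu2| / max(sigma1, sigma2) — a
separation-to-spread ratio, a rough analog of a t-statistic — and a weight
balance flag |w1 - w2| < 0.25 requiring both expression states to contain
comparable fractions of the cohort.  Genes passing both gates are ranked by
descending score and the top ``top_k`` selected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._dip import DipNullDistribution, dip_statistic
from .mixture import NormalMixtureResults, TwoComponentNormalMixture

__all__ = ["bimodal_score", "weight_criterion", "screen_genes"]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "gene_id",
    "n_obs",
    "dip_stat",
    "dip_p",
    "mu1",
    "mu2",
    "sigma1",
    "sigma2",
    "w1",
    "w2",
    "loglik",
    "converged",
    "score",
    "weight_ok",
    "rank",
]


def bimodal_score(fit: NormalMixtureResults) -> float:
    """Separation-to-spread score |mu1 - mu2| / max(sigma1, sigma2).

    Invariant under positive affine transforms of the data and zero when the
    two component means coincide.
    """
    return abs(fit.mu1 - fit.mu2) / max(fit.sigma1, fit.sigma2)


def weight_criterion(fit: NormalMixtureResults, max_diff: float = 0.25) -> bool:
    """True iff the component weights are balanced: |w1 - w2| < max_diff.

    The inequality is strict, so a fit sitting exactly on the boundary
    (e.g. w1 = 0.625) fails.
    """
    return bool(abs(fit.w1 - fit.w2) < max_diff)


def _low_expression_mask(values: np.ndarray, max_tie_frac: float) -> bool:
    """True when the gene should be excluded: too many samples tied at the minimum.

    Point masses at the detection floor (all-zero FPKM) break the mixture
    model, so genes with more than ``max_tie_frac`` of their finite values
    equal to the minimum are filtered out before dip testing.
    """
    v = values[np.isfinite(values)]
    if v.size == 0:
        return True
    return np.mean(v == v.min()) > max_tie_frac


def screen_genes(
    matrix: pd.DataFrame,
    alpha_dip: float = 0.05,
    top_k: int = 200,
    n_boot: int = 2000,
    rng=None,
    min_expression_filter: bool = True,
    max_tie_frac: float = 0.20,
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
    em_var_floor: float = 1e-3,
    em_n_starts: int = 5,
) -> pd.DataFrame:
    """Screen every gene of an expression matrix for bimodality.

    Parameters
    ----------
    matrix : pandas.DataFrame
        genes x samples expression on the log2(FPKM + 1) scale, gene ids as
        index.  Missing entries (NaN) are dropped per gene; every gene needs
        at least 10 non-missing values.
    alpha_dip : float
        Dip-test significance gate; the mixture is fitted only below it.
    top_k : int
        Maximum number of ranked records.
    n_boot : int
        Monte-Carlo replicates for the dip null distribution.  One null
        table is simulated per distinct per-gene sample size and shared.
    rng : seed or numpy Generator
        Drives the dip null simulation and EM restarts.

    Returns
    -------
    pandas.DataFrame
        One row per gene with dip statistic/p, mixture parameters, score,
        weight flag, and ``rank`` (1-based, NaN for unranked genes).  Genes
        are ranked by descending score, ties broken by gene id, only if
        ``dip_p < alpha_dip`` and the weight criterion holds.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rng = np.random.default_rng(rng)

    values = matrix.to_numpy(dtype=float)
    finite_counts = np.isfinite(values).sum(axis=1)
    if (finite_counts < 10).any():
        offenders = matrix.index[finite_counts < 10].tolist()
        raise ValueError(
            f"genes with fewer than 10 non-missing values: {offenders[:5]}"
        )

    null_tables: dict[int, DipNullDistribution] = {}
    # reserve one child seed per purpose so gene order does not shift draws
    null_seed, em_seed = rng.spawn(2)
    em_rngs = em_seed.spawn(len(matrix.index))

    n_filtered = 0
    rows = []
    for i, gene in enumerate(matrix.index):
        v = values[i]
        v = v[np.isfinite(v)]
        row = {c: np.nan for c in RECORD_COLUMNS}
        row["gene_id"] = gene
        row["n_obs"] = v.size
        row["weight_ok"] = False
        row["converged"] = False
        if min_expression_filter and _low_expression_mask(v, max_tie_frac):
            n_filtered += 1
            rows.append(row)
            continue
        if np.all(v == v[0]):
            n_filtered += 1
            rows.append(row)
            continue
        d = dip_statistic(v)
        n = v.size
        if n not in null_tables:
            null_tables[n] = DipNullDistribution(n, n_boot=n_boot, rng=null_seed)
        p = null_tables[n].pvalue(d)
        row["dip_stat"] = d
        row["dip_p"] = p
        if p < alpha_dip:
            fit = TwoComponentNormalMixture(v).fit(
                tol=em_tol,
                max_iter=em_max_iter,
                var_floor=em_var_floor,
                n_starts=em_n_starts,
                rng=em_rngs[i],
            )
            row.update(
                mu1=fit.mu1,
                mu2=fit.mu2,
                sigma1=fit.sigma1,
                sigma2=fit.sigma2,
                w1=fit.w1,
                w2=fit.w2,
                loglik=fit.loglik,
                converged=fit.converged,
                score=bimodal_score(fit),
                weight_ok=weight_criterion(fit),
            )
        rows.append(row)

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if n_filtered:
        logger.info(
            "low-expression pre-filter excluded %d/%d genes (> %.0f%% tied at minimum)",
            n_filtered,
            len(records),
            100 * max_tie_frac,
        )

    eligible = records[
        (records["dip_p"] < alpha_dip) & (records["weight_ok"] == True)  # noqa: E712
    ].copy()
    eligible = eligible.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    ranked_ids = eligible["gene_id"].head(top_k)
    rank_map = {g: r for r, g in enumerate(ranked_ids, start=1)}
    records["rank"] = records["gene_id"].map(rank_map).astype("float64")
    logger.info(
        "dip-significant: %d, weight-eligible: %d, ranked: %d (top_k=%d)",
        int((records["dip_p"] < alpha_dip).sum()),
        len(eligible),
        len(rank_map),
        top_k,
    )
    return records
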