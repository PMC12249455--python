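"""End-to-end screening cascade as a model/results pair.

:class:`BimodalPrognosticScreen` holds an expression matrix and matched
clinical table; :meth:`fit` runs the full cascade — optional batch-effect
removal, per-gene bimodality screen, median-split survival screen of the
ranked genes, reference-gene (MKI67) correlation partition, and the pathway
average-expression survival score — and returns a
:class:`BimodalPrognosticResults` carrying every stage table, the headline
counts and a text summary.  ``run_pipeline`` wraps it for config-file /
CLI use and writes all artifacts to disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_PATHWAY_GENES,
    partition_by_reference,
    pathway_average_survival,
)
from .bimodality import screen_genes
from .io import PipelineConfig, read_clinical, read_expression, remove_batch_effect
from .survival import survival_screen

__all__ = ["BimodalPrognosticScreen", "BimodalPrognosticResults", "run_pipeline"]

logger = logging.getLogger(__name__)


class BimodalPrognosticResults:
    """Fitted cascade: stage tables, counts, summary and writers."""

    def __init__(self, records, survival, counts, partition, pathway, config):
        self.records = records  # per-gene bimodality records
        self.survival = survival  # per-ranked-gene survival results
        self.counts = counts  # headline cascade counts
        self.partition = partition  # reference-gene correlation partition
        self.pathway = pathway  # pathway-average survival result (or None)
        self.config = config

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Bimodal prognostic screen",
            "=" * 46,
            f"{'genes screened':<34}{c['n_genes']:>12}",
            f"{'dip-significant genes':<34}{c['n_dip_significant']:>12}",
            f"{'weight-balanced (ranked pool)':<34}{c['n_eligible']:>12}",
            f"{'ranked (top_k kept)':<34}{c['n_ranked']:>12}",
            f"{'survival-significant':<34}{c['n_significant']:>12}",
            f"{'  poor prognosis (HR > 1)':<34}{c['n_poor']:>12}",
            f"{'  good prognosis (HR < 1)':<34}{c['n_good']:>12}",
            f"{'multivariate-robust':<34}{c['n_multivariate_robust']:>12}",
        ]
        if "n_low_reference_corr" in c:
            lines.append(
                f"{'low reference correlation':<34}{c['n_low_reference_corr']:>12}"
            )
        if self.pathway is not None and self.pathway.get("estimable"):
            lines.append("-" * 46)
            lines.append(
                f"pathway score HR {self.pathway['hr']:.2f} "
                f"[{self.pathway['ci_low']:.2f}, {self.pathway['ci_high']:.2f}], "
                f"log-rank p {self.pathway['p_logrank']:.3g}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write stage TSVs and the JSON summary; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(df, name):
            p = out / name
            df.to_csv(p, sep="\t", index=False, na_rep="NA", float_format="%.10g")
            paths[name] = str(p)

        _write(self.records, "bimodal_records.tsv")
        _write(self.survival, "survival_results.tsv")
        if self.partition is not None:
            _write(self.partition["correlations"], "reference_partition.tsv")
        summary = {"counts": self.counts, "config": self.config.to_dict(),
                   "version": __version__}
        if self.pathway is not None:
            summary["pathway"] = {
                k: self.pathway[k]
                for k in ("feature_id", "hr", "ci_low", "ci_high", "p_wald",
                          "p_logrank", "concordance", "estimable")
            }
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        paths["summary.json"] = str(p)
        return paths


class BimodalPrognosticScreen:
    """Bimodal-gene prognostic screening model for one cohort.

    Parameters
    ----------
    expression : pandas.DataFrame
        genes x samples log2(FPKM + 1) matrix.
    clinical : pandas.DataFrame
        Per-sample table with sample_id, os_time (months), os_event (0/1),
        age, stage, gender and optionally batch.  Sample ids must match the
        matrix columns exactly (strict; intersect upstream if needed).
    config : PipelineConfig, optional
        Thresholds and parameters; defaults are the standard cascade
        (dip alpha 0.05, top 200, survival alpha 0.05, |r| < 0.3).
    """

    def __init__(self, expression, clinical, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        clin = clinical.copy()
        if "sample_id" not in clin.columns:
            raise ValueError("clinical table needs a sample_id column")
        clin["sample_id"] = clin["sample_id"].astype(str)
        mismatch = set(map(str, expression.columns)) ^ set(clin["sample_id"])
        if mismatch:
            raise ValueError(
                "sample ids do not match between expression and clinical: "
                f"{sorted(mismatch)[:5]}"
            )
        self.expression = expression
        self.clinical = clin

    def fit(self) -> BimodalPrognosticResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        matrix = self.expression

        if cfg.batch_correct and "batch" in self.clinical.columns:
            batches = self.clinical.set_index("sample_id").loc[
                matrix.columns, "batch"
            ]
            if batches.nunique() > 1:
                logger.info("removing additive batch effects (%d batches)",
                            batches.nunique())
                matrix = remove_batch_effect(matrix, batches)

        records = screen_genes(
            matrix,
            alpha_dip=cfg.alpha_dip,
            top_k=cfg.top_k,
            n_boot=cfg.n_boot,
            rng=rng,
            min_expression_filter=cfg.min_expression_filter,
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            em_n_starts=cfg.em_n_starts,
        )
        survival, surv_counts = survival_screen(
            records,
            matrix,
            self.clinical,
            alpha=cfg.alpha_surv,
            stage_ordinal=cfg.stage_ordinal,
        )
        counts = {
            "n_genes": int(len(records)),
            "n_dip_significant": int((records["dip_p"] < cfg.alpha_dip).sum()),
            "n_eligible": int(
                ((records["dip_p"] < cfg.alpha_dip) & records["weight_ok"]).sum()
            ),
            "n_ranked": int(records["rank"].notna().sum()),
            **surv_counts,
        }

        partition = None
        sig_genes = survival.loc[survival["significant"], "feature_id"].tolist()
        if cfg.reference_gene in matrix.index and sig_genes:
            partition = partition_by_reference(
                sig_genes,
                matrix,
                reference_gene=cfg.reference_gene,
                r_threshold=cfg.r_threshold,
            )
            counts["n_low_reference_corr"] = len(partition["low_correlated"])

        pathway = None
        pathway_genes = cfg.pathway_genes or DEFAULT_PATHWAY_GENES
        if all(g in matrix.index for g in pathway_genes):
            pathway = pathway_average_survival(matrix, self.clinical, pathway_genes)

        return BimodalPrognosticResults(
            records, survival, counts, partition, pathway, cfg
        )


def run_pipeline(config: PipelineConfig) -> BimodalPrognosticResults:
    """Load inputs per config, fit the cascade, write artifacts to out_dir."""
    if config.expr_path is None or config.clinical_path is None:
        raise ValueError("config must provide expr_path and clinical_path")
    logger.info("pipeline start: %s", config.to_dict())
    matrix = read_expression(config.expr_path)
    clinical = read_clinical(config.clinical_path)
    model = BimodalPrognosticScreen(matrix, clinical, config)
    results = model.fit()
    results.save(config.out_dir)
    logger.info("pipeline done: %s", results.counts)
    return results
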