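"""Readers, writers, batch-effect removal and pipeline configuration.

Expression matrices travel as TSV (first column gene id, header row of
sample ids, blank or ``NA`` cells for missing); clinical tables as CSV with
one row per sample.  Batch effects are removed additively per gene:
regress out a batch indicator with no other covariates and restore the
grand mean.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "remove_batch_effect",
    "PipelineConfig",
]

CLINICAL_COLUMNS = ["sample_id", "os_time", "os_event", "age", "stage", "gender"]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (or CSV by extension).

    Duplicate gene or sample ids and non-numeric cells are rejected with
    the offending identifier; blank and ``NA`` cells become missing.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene ids: {dup_genes[:5]}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample ids: {dup_samples[:5]}")
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric cell at gene {df.index[bad.argmax()]!r}, "
                    f"sample {col!r}: {df[col][bad].iloc[0]!r}"
                ) from None
        raise
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV, gene ids in the first column."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path) -> pd.DataFrame:
    """Read a per-sample clinical CSV; checks required columns and id uniqueness."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    dups = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
    if (df["os_time"] <= 0).any():
        bad = df.loc[df["os_time"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive survival times for samples: {bad[:5]}")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be binary 0/1")
    return df


def remove_batch_effect(matrix: pd.DataFrame, batch_labels) -> pd.DataFrame:
    """Subtract per-gene additive batch means, restoring the grand mean.

    Equivalent to regressing each gene on a batch indicator with no other
    covariates and keeping the residual plus intercept.  Requires >= 2
    batches represented... a single shared label returns the matrix
    unchanged; a batch with < 2 samples raises.
    """
    batch = pd.Series(np.asarray(batch_labels), index=matrix.columns)
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if len(sizes) == 1:
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    out = np.array(vals)
    grand = np.nanmean(vals, axis=1, keepdims=True)
    for b in sizes.index:
        cols = (batch == b).to_numpy()
        bmean = np.nanmean(vals[:, cols], axis=1, keepdims=True)
        out[:, cols] = vals[:, cols] - bmean + grand
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class PipelineConfig:
    """Thresholds, parameters and paths for the full screening cascade."""

    expr_path: str | None = None
    clinical_path: str | None = None
    out_dir: str = "results"
    alpha_dip: float = 0.05
    top_k: int = 200
    alpha_surv: float = 0.05
    r_threshold: float = 0.3
    n_boot: int = 2000
    reference_gene: str = "MKI67"
    pathway_genes: tuple = ()
    batch_correct: bool = True
    min_expression_filter: bool = True
    stage_ordinal: bool = False
    em_n_starts: int = 5
    em_tol: float = 1e-8
    em_max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_dip", "alpha_surv", "r_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.pathway_genes = tuple(self.pathway_genes)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_genes"] = list(self.pathway_genes)
        return d
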