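"""Median-dichotomized proportional-hazards screening of candidate genes.

Expression is split at the per-gene median into high/low groups; group
survival is compared by the log-rank test and a Cox proportional-hazards
fit of the binary high-vs-low indicator (low = reference), reporting the
hazard ratio, 95% Wald confidence interval, Wald p, log-rank p and
Harrell's concordance.  HR > 1 marks the high-expression state as the
poor-prognosis state.  Significant genes are re-tested with a multivariate
Cox model adjusting for age (years), tumor stage (advanced III/IV vs
localized I/II) and gender.  Cox fits use lifelines with the Efron tie
approximation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

__all__ = [
    "median_dichotomize",
    "logrank_test",
    "univariate_cox",
    "multivariate_cox",
    "km_curve",
    "survival_screen",
    "SurvivalResult",
]

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = [
    "feature_id",
    "hr",
    "ci_low",
    "ci_high",
    "p_wald",
    "p_logrank",
    "concordance",
    "n_high",
    "n_low",
    "direction",
    "estimable",
]


class SurvivalResult(dict):
    """Dict-like survival summary with attribute access."""

    __getattr__ = dict.__getitem__


def median_dichotomize(values) -> np.ndarray:
    """Split values at their median: 1 (high) iff value > median.

    Ties at the median go to the low group — deterministic and conservative
    for the high-risk call.  Requires >= 4 non-missing, not all identical.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("median split needs >= 4 non-missing values")
    if np.all(v[finite] == v[finite][0]):
        raise ValueError("degenerate split: all values identical")
    med = np.median(v[finite])
    labels = np.where(v > med, 1, 0)
    labels = np.where(finite, labels, -1)  # -1 marks missing
    if (labels[finite] == 1).sum() == 0:
        # > half the values tied at the max; split at > becomes empty
        raise ValueError("degenerate split: no values above the median")
    return labels


def logrank_test(labels, os_time, os_event):
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    labels = np.asarray(labels)
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    g1, g0 = labels == 1, labels == 0
    if g1.sum() == 0 or g0.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if e[g1 | g0].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(t[g1], t[g0], event_observed_A=e[g1], event_observed_B=e[g0])
    return float(res.test_statistic), float(res.p_value)


def _cox_fit(df, duration_col, event_col, robust_cols=None):
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def univariate_cox(labels, os_time, os_event) -> SurvivalResult:
    """Cox PH fit of the binary high/low indicator (low = reference).

    Non-estimable situations (no events, complete separation, failed
    convergence) return a flagged result with ``estimable=False`` rather
    than raising.
    """
    labels = np.asarray(labels)
    keep = labels >= 0
    df = pd.DataFrame(
        {
            "group": labels[keep].astype(float),
            "time": np.asarray(os_time, dtype=float)[keep],
            "event": np.asarray(os_event, dtype=int)[keep],
        }
    )
    n_high = int((df["group"] == 1).sum())
    n_low = int((df["group"] == 0).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must be non-empty")
    try:
        stat, p_lr = logrank_test(df["group"].to_numpy(), df["time"], df["event"])
    except ValueError:
        p_lr = np.nan
    base = dict(
        feature_id=None,
        n_high=n_high,
        n_low=n_low,
        p_logrank=p_lr,
        estimable=False,
        hr=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_wald=np.nan,
        concordance=np.nan,
        direction=None,
    )
    if df["event"].sum() == 0:
        return SurvivalResult(base)
    try:
        cph = _cox_fit(df, "time", "event")
    except Exception as exc:  # convergence / separation
        logger.info("univariate Cox non-estimable: %s", exc)
        return SurvivalResult(base)
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 100:
        return SurvivalResult(base)
    hr = float(np.exp(coef))
    base.update(
        hr=hr,
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p_wald=float(cph.summary.loc["group", "p"]),
        concordance=float(cph.concordance_index_),
        direction="poor" if hr > 1 else "good",
        estimable=True,
    )
    return SurvivalResult(base)


def encode_stage(stage, ordinal: bool = False) -> pd.Series:
    """Encode tumor stage: binary advanced (III/IV = 1) vs localized (I/II = 0).

    Missing/NA stays NaN.  ``ordinal=True`` returns I..IV as 1..4 instead.
    """
    s = pd.Series(stage).astype("string")
    order = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}
    num = s.map(order)
    if ordinal:
        return num.astype(float)
    return (num >= 3).astype(float).where(num.notna())


def multivariate_cox(
    labels, os_time, os_event, age, stage, gender, stage_ordinal: bool = False
) -> SurvivalResult:
    """Cox PH fit of the gene indicator adjusted for age, stage and gender.

    Stage enters as binary advanced (III/IV) vs localized (I/II) unless
    ``stage_ordinal``; samples with missing stage are dropped (complete
    case) and the count logged.  The returned result describes the gene
    term; covariate coefficients are attached under ``covariates``.
    """
    labels = np.asarray(labels)
    df = pd.DataFrame(
        {
            "group": labels.astype(float),
            "time": np.asarray(os_time, dtype=float),
            "event": np.asarray(os_event, dtype=int),
            "age": np.asarray(age, dtype=float),
            "stage_adv": encode_stage(stage, ordinal=stage_ordinal).to_numpy(),
            "male": (pd.Series(gender).astype(str).str.lower() == "male").astype(float),
        }
    )
    df = df[df["group"] >= 0]
    n_drop = int(df["stage_adv"].isna().sum() + df["age"].isna().sum())
    df = df.dropna()
    if n_drop:
        logger.info("multivariate Cox: dropped %d samples with missing covariates", n_drop)
    n_high = int((df["group"] == 1).sum())
    n_low = int((df["group"] == 0).sum())
    base = dict(
        feature_id=None,
        n_high=n_high,
        n_low=n_low,
        p_logrank=np.nan,
        estimable=False,
        hr=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_wald=np.nan,
        concordance=np.nan,
        direction=None,
        covariates=None,
    )
    if n_high == 0 or n_low == 0 or df["event"].sum() == 0:
        return SurvivalResult(base)
    try:
        cph = _cox_fit(df, "time", "event")
    except Exception as exc:
        logger.info("multivariate Cox non-estimable: %s", exc)
        return SurvivalResult(base)
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 100:
        return SurvivalResult(base)
    hr = float(np.exp(coef))
    base.update(
        hr=hr,
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p_wald=float(cph.summary.loc["group", "p"]),
        concordance=float(cph.concordance_index_),
        direction="poor" if hr > 1 else "good",
        estimable=True,
        covariates=cph.summary[["coef", "se(coef)", "p"]].to_dict("index"),
    )
    return SurvivalResult(base)


def km_curve(labels, os_time, os_event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimates per group.

    Returns a tidy frame with columns group, time, survival, at_risk — the
    right-continuous step function starting at survival 1.
    """
    labels = np.asarray(labels)
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    frames = []
    for grp, name in ((0, "low"), (1, "high")):
        mask = labels == grp
        if mask.sum() == 0:
            raise ValueError(f"group '{name}' is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def survival_screen(
    records: pd.DataFrame,
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    stage_ordinal: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Median-split survival screen of the ranked bimodal genes.

    For every ranked gene: median dichotomization, log-rank test and
    univariate Cox; a gene is *significant* iff its log-rank p < ``alpha``.
    Significant genes are partitioned by hazard direction (HR > 1 poor,
    HR < 1 good) and re-tested with the covariate-adjusted model; *robust*
    means adjusted gene p < ``alpha``.  Benjamini-Hochberg adjusted log-rank
    p-values are reported alongside for reference (no correction is applied
    to the gates).

    Returns ``(results, counts)`` with counts n_tested, n_significant,
    n_poor, n_good, n_multivariate_robust.
    """
    ranked = records.dropna(subset=["rank"]).sort_values("rank")
    if len(ranked) == 0:
        raise ValueError("no ranked genes to screen")
    missing = set(ranked["gene_id"]) - set(matrix.index)
    if missing:
        raise ValueError(f"ranked genes absent from matrix: {sorted(missing)[:5]}")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical else clinical
    mismatch = set(matrix.columns) ^ set(clin.index)
    if mismatch:
        raise ValueError(
            f"sample ids do not match between matrix and clinical: {sorted(mismatch)[:5]}"
        )
    clin = clin.loc[matrix.columns]

    rows = []
    for _, rec in ranked.iterrows():
        gene = rec["gene_id"]
        values = matrix.loc[gene].to_numpy(dtype=float)
        labels = median_dichotomize(values)
        uni = univariate_cox(labels, clin["os_time"], clin["os_event"])
        row = {
            "feature_id": gene,
            "rank": rec["rank"],
            "score": rec.get("score", np.nan),
            **{k: uni[k] for k in SURVIVAL_COLUMNS if k != "feature_id"},
        }
        row["significant"] = bool(
            np.isfinite(uni["p_logrank"]) and uni["p_logrank"] < alpha
        )
        if row["significant"]:
            adj = multivariate_cox(
                labels,
                clin["os_time"],
                clin["os_event"],
                clin["age"],
                clin["stage"],
                clin["gender"],
                stage_ordinal=stage_ordinal,
            )
            row.update(
                adj_hr=adj["hr"],
                adj_ci_low=adj["ci_low"],
                adj_ci_high=adj["ci_high"],
                adj_p=adj["p_wald"],
                robust=bool(np.isfinite(adj["p_wald"]) and adj["p_wald"] < alpha),
            )
        else:
            row.update(
                adj_hr=np.nan, adj_ci_low=np.nan, adj_ci_high=np.nan,
                adj_p=np.nan, robust=False,
            )
        rows.append(row)
    results = pd.DataFrame(rows)
    ok = results["p_logrank"].notna()
    results["p_logrank_bh"] = np.nan
    if ok.any():
        results.loc[ok, "p_logrank_bh"] = multipletests(
            results.loc[ok, "p_logrank"], method="fdr_bh"
        )[1]

    sig = results[results["significant"]]
    counts = {
        "n_tested": int(len(results)),
        "n_significant": int(len(sig)),
        "n_poor": int((sig["direction"] == "poor").sum()),
        "n_good": int((sig["direction"] == "good").sum()),
        "n_multivariate_robust": int(sig["robust"].sum()),
    }
    logger.info("survival screen: %s", counts)
    return results, counts
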