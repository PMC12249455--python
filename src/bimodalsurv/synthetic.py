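"""Seeded synthetic cohorts with planted bimodal prognostic genes.

The generator inverts the model the screening pipeline assumes: per-gene
expression on the log2(FPKM + 1) scale is drawn either from a single normal
(background genes) or from a two-component normal mixture (planted bimodal
genes), and overall survival follows an exponential proportional-hazards
model in which a sample's mixture-component membership multiplies the
baseline hazard by exp(log_hr).  Right censoring is administrative: uniform
on [0, T_max] with T_max solved numerically so the expected censored
fraction matches ``censor_rate``.

Defaults mirror an adrenocortical-carcinoma-scale cohort: 112 samples, a
median overall survival of about 43 months in the reference group
(baseline hazard ln 2 / 43 per month), about one third of patients with an
observed death, two batches sized like a 79 + 33 two-source cohort, and
clinical covariates (age, binary localized/advanced stage, gender, hormone
status) with realistic prevalences.  Planted prognostic genes share one
latent component membership by default — a two-subtype cohort in which the
same patient subpopulation expresses the high state of every prognostic
gene and carries the elevated hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "plant_bimodal_gene",
    "simulate_survival",
    "generate_cohort",
]

#: per-month hazard giving median overall survival of 43 months
DEFAULT_BASELINE_HAZARD = float(np.log(2.0) / 43.0)


@dataclass
class SimulationConfig:
    """Ground-truth description of a synthetic cohort.

    Attributes
    ----------
    n_samples, n_genes, n_bimodal : int
        Cohort size, total genes, and number of planted bimodal genes.
    n_prognostic : int or None
        How many of the planted bimodal genes drive survival (defaults to
        all of them).
    mixture_params : tuple
        (mu1, mu2, sigma1, sigma2, w1) for every planted gene, in
        log2(FPKM + 1) units.
    background_params : tuple
        (mu, sigma) of the single normal for unimodal genes.
    log_hr : float
        Log hazard ratio of the high component vs the low component.
    baseline_hazard : float
        Events per month in the low component.
    censor_rate : float
        Expected censored fraction, in [0, 1).
    shared_membership : bool
        If True (default) all prognostic genes express the same latent
        two-group patient structure and the hazard depends on that single
        label; if False each planted gene draws independent memberships and
        the log hazard ratios of prognostic genes add.
    batch_sizes, batch_offsets : tuple
        Per-batch sample counts (must sum to n_samples) and additive
        expression shifts applied to every gene.
    age_mean, age_sd, advanced_stage_rate, female_rate, hormone_rate : float
        Clinical covariate distributions (age in years).
    age_log_hr, stage_log_hr : float
        Optional covariate effects on the hazard (defaults 0: covariates
        carry no prognostic signal unless asked for).
    seed : int
        Drives every draw; identical (config, seed) gives an identical
        cohort.
    """

    n_samples: int = 112
    n_genes: int = 2000
    n_bimodal: int = 50
    n_prognostic: int | None = None
    mixture_params: tuple = (2.0, 6.0, 1.0, 1.0, 0.5)
    background_params: tuple = (4.0, 1.0)
    log_hr: float = float(np.log(4.27))
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    censor_rate: float = 0.67
    shared_membership: bool = True
    batch_sizes: tuple = (79, 33)
    batch_offsets: tuple = (0.0, 0.0)
    age_mean: float = 47.0
    age_sd: float = 12.0
    advanced_stage_rate: float = 0.43
    female_rate: float = 0.69
    hormone_rate: float = 0.65
    age_log_hr: float = 0.0
    stage_log_hr: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bimodal > self.n_genes:
            raise ValueError("n_bimodal cannot exceed n_genes")
        if self.n_prognostic is None:
            self.n_prognostic = self.n_bimodal
        if self.n_prognostic > self.n_bimodal:
            raise ValueError("n_prognostic cannot exceed n_bimodal")
        mu1, mu2, s1, s2, w1 = self.mixture_params
        if s1 <= 0 or s2 <= 0:
            raise ValueError("mixture sigmas must be positive")
        if not 0.0 < w1 < 1.0:
            raise ValueError("mixture weight w1 must lie in (0, 1)")
        if self.background_params[1] <= 0:
            raise ValueError("background sigma must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if sum(self.batch_sizes) != self.n_samples:
            raise ValueError("batch_sizes must sum to n_samples")
        if len(self.batch_offsets) != len(self.batch_sizes):
            raise ValueError("batch_offsets and batch_sizes must align")


@dataclass
class SyntheticCohort:
    """Expression + clinical tables plus the full planted ground truth."""

    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # one row per sample
    truth: pd.DataFrame  # one row per gene
    membership: pd.DataFrame  # samples x prognostic-relevant planted genes
    config: SimulationConfig = field(repr=False, default=None)


def plant_bimodal_gene(mu1, mu2, sigma1, sigma2, w1, n, rng):
    """Draw one gene from a two-component normal mixture.

    Returns ``(values, labels)`` where ``labels`` is 0 for component 1
    (probability ``w1``) and 1 for component 2.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    if not 0.0 < w1 < 1.0:
        raise ValueError("w1 must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(rng)
    labels = (rng.random(n) >= w1).astype(int)
    mu = np.where(labels == 0, mu1, mu2)
    sigma = np.where(labels == 0, sigma1, sigma2)
    return rng.normal(mu, sigma), labels


def _solve_tmax(rates, censor_rate):
    """Administrative censoring horizon hitting the target censored fraction.

    With event time T ~ Exp(rate) and censoring C ~ Uniform(0, T_max),
    P(censored) = E[exp(-rate * C)] = (1 - exp(-rate*T_max)) / (rate*T_max);
    averaged over the per-sample rates this decreases from 1 to 0 in T_max,
    so the root is unique.
    """

    def expected_censored(tmax):
        rt = rates * tmax
        return float(np.mean(np.where(rt > 1e-12, (1.0 - np.exp(-rt)) / rt, 1.0)))

    hi = 1.0
    while expected_censored(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            break
    return brentq(lambda t: expected_censored(t) - censor_rate, 1e-9, hi)


def simulate_survival(
    component_labels, baseline_hazard, log_hr, censor_rate, rng, extra_linpred=0.0
):
    """Exponential survival with hazard baseline * exp(log_hr * label).

    ``component_labels`` may be binary (one prognostic label per sample) or
    a samples x genes matrix of binary labels, in which case the per-gene
    log hazard ratios add on the log scale.  ``extra_linpred`` adds further
    per-sample terms (e.g. covariate effects) to the log hazard.  Returns
    ``(time, event)`` in months with administrative-uniform right censoring
    calibrated so the expected censored fraction equals ``censor_rate``.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    labels = np.asarray(component_labels)
    if labels.ndim == 1:
        linpred = log_hr * labels.astype(float)
    else:
        linpred = labels.astype(float) @ np.broadcast_to(
            np.asarray(log_hr, dtype=float), (labels.shape[1],)
        )
    linpred = linpred + extra_linpred
    rates = baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0.0:
        return t_event, np.ones(t_event.size, dtype=int)
    tmax = _solve_tmax(rates, censor_rate)
    t_censor = rng.uniform(0.0, tmax, size=t_event.size)
    event = (t_event <= t_censor).astype(int)
    return np.minimum(t_event, t_censor), event


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`SimulationConfig`."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    mu1, mu2, s1, s2, w1 = cfg.mixture_params
    bg_mu, bg_sd = cfg.background_params

    gene_ids = [f"BIM{i:04d}" for i in range(cfg.n_bimodal)] + [
        f"BG{i:05d}" for i in range(g - cfg.n_bimodal)
    ]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    expr = np.empty((g, n))
    is_bimodal = np.zeros(g, dtype=bool)
    is_prognostic = np.zeros(g, dtype=bool)
    is_bimodal[: cfg.n_bimodal] = True
    is_prognostic[: cfg.n_prognostic] = True

    shared_label = (rng.random(n) >= w1).astype(int) if cfg.shared_membership else None
    memberships = {}
    for i in range(cfg.n_bimodal):
        if cfg.shared_membership and is_prognostic[i]:
            labels = shared_label
            mu = np.where(labels == 0, mu1, mu2)
            sd = np.where(labels == 0, s1, s2)
            expr[i] = rng.normal(mu, sd)
        else:
            expr[i], labels = plant_bimodal_gene(mu1, mu2, s1, s2, w1, n, rng)
        memberships[gene_ids[i]] = labels
    expr[cfg.n_bimodal :] = rng.normal(bg_mu, bg_sd, size=(g - cfg.n_bimodal, n))

    # batches and covariates (drawn before survival so they can enter the hazard)
    batch = np.repeat(
        [f"batch{k}" for k in range(len(cfg.batch_sizes))], cfg.batch_sizes
    )
    offsets = np.repeat(np.asarray(cfg.batch_offsets, dtype=float), cfg.batch_sizes)
    expr += offsets[None, :]

    age = rng.normal(cfg.age_mean, cfg.age_sd, n).round(1)
    advanced = rng.random(n) < cfg.advanced_stage_rate
    stage = np.where(
        advanced,
        rng.choice(["III", "IV"], size=n),
        rng.choice(["I", "II"], size=n),
    )
    gender = np.where(rng.random(n) < cfg.female_rate, "female", "male")
    hormone = np.where(rng.random(n) < cfg.hormone_rate, "yes", "no")

    # survival driven by the prognostic memberships plus optional covariate effects
    if cfg.n_prognostic == 0:
        surv_labels = np.zeros(n, dtype=int)
        log_hr = 0.0
    elif cfg.shared_membership:
        surv_labels = shared_label
        log_hr = cfg.log_hr
    else:
        surv_labels = np.column_stack(
            [memberships[gene_ids[i]] for i in range(cfg.n_prognostic)]
        )
        log_hr = np.full(cfg.n_prognostic, cfg.log_hr)
    covariate_linpred = cfg.age_log_hr * (age - cfg.age_mean) + cfg.stage_log_hr * advanced
    os_time, os_event = simulate_survival(
        surv_labels,
        cfg.baseline_hazard,
        log_hr,
        cfg.censor_rate,
        rng,
        extra_linpred=covariate_linpred,
    )

    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "stage": stage,
            "gender": gender,
            "hormone": hormone,
            "batch": batch,
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_bimodal": is_bimodal,
            "is_prognostic": is_prognostic,
            "mu1": np.where(is_bimodal, mu1, bg_mu),
            "mu2": np.where(is_bimodal, mu2, bg_mu),
            "sigma1": np.where(is_bimodal, s1, bg_sd),
            "sigma2": np.where(is_bimodal, s2, bg_sd),
            "w1": np.where(is_bimodal, w1, np.nan),
            "log_hr": np.where(is_prognostic, cfg.log_hr, 0.0),
        }
    )
    membership = pd.DataFrame(memberships, index=sample_ids)
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth=truth,
        membership=membership,
        config=cfg,
    )
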