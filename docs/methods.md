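# Methods

`bimodalsurv` implements a biomarker-discovery cascade for bulk RNA-seq
cohorts in which a gene's expression, on the log2(FPKM + 1) scale, splits
the patients into two states — a low-expressing and a high-expressing
subpopulation — and the state carries prognostic information. The cascade
is: unimodality screen → mixture fit and bimodal score → ranked selection →
median-split survival screen → proliferation-marker partition → pathway
score. This note records the models, the defaults and the numerical
choices, and what the synthetic-cohort experiments do and do not show.

## Dip statistic and its null distribution

For a sample x₁…xₙ the dip D is the smallest sup-norm distance between the
empirical CDF and any *unimodal* CDF (convex up to a mode, concave after
it, with at most one atom, located at the mode). We compute it with the
classical alternating-fit algorithm: fit the greatest convex minorant (GCM)
and least concave majorant (LCM) of the ECDF on a candidate modal interval,
take the largest GCM/LCM separation, accumulate the ECDF deviations from
the two hulls on the flanks outside the modal interval, and shrink the
interval until the separation no longer exceeds the running maximum. All
bookkeeping is on the count scale and the final statistic is the maximal
deviation divided by 2n, so n distinct points compatible with unimodality
attain the lower bound 1/(2n) and two equal point masses attain the upper
bound 1/4.

The implementation is validated against a reference that minimizes the
sup-distance literally (`bimodalsurv._dip_reference`): for each candidate
mode position — every data point, plus a refined grid inside every
between-point gap, since an atom strictly between observations can be
optimal — the best-fitting shape-constrained CDF is a linear program in the
fitted values. Fast algorithm and reference agree to ≤ 1e-6 on hundreds of
random samples (normal, uniform, bimodal, tie-heavy, skewed) up to n = 112.
Two subtleties the reference has to model explicitly: the mode may carry an
atom (so the fitted CDF has distinct left and right limits there), and a
mode placed inside a gap still constrains the convex branch to keep
climbing into it and the concave branch to start from it.

P-values are Monte Carlo against the standard null, Uniform(0,1) samples of
the same size: p = (1 + #{null dips ≥ observed}) / (B + 1), default
B = 2000. Because the null depends only on n, a screen simulates one null
table per distinct per-gene sample size and reuses it
(`DipNullDistribution`). Two calibration facts worth knowing:

- Under the uniform null the test is exact by exchangeability
  (per-replicate rejection probability 100/2001 at α = 0.05). A replication
  study that shares *one* simulated table across all replicates inherits
  that table's critical-value error as a common shift; the calibration
  experiments therefore rotate 20 independent tables.
- For *non-uniform* unimodal data the test is conservative: normal-
  distributed genes reject at well under 1% at α = 0.05 and n = 112. A
  background of normal genes therefore produces far fewer dip-significant
  false positives than α · n_genes.

Power is the binding constraint of the whole cascade. At n = 112 and
α = 0.05 the dip gate detects a balanced two-component mixture with
separation |µ₂ − µ₁| = 4·max(σ) about 79% of the time (score 3: ~12%;
score 2: ~2%). Downstream recall of planted bimodal genes is capped by
these numbers no matter how well the mixture fit and ranking behave; the
acceptance suite documents a measured top-200 recall of ~0.80–0.88 for
score-4 genes, below the 90% one might hope for, and the per-seed value is
reported by `scripts/acceptance.py`.

## Two-component mixture and the bimodal score

Genes passing the dip gate are fitted with
f(x) = w₁·N(µ₁, σ₁²) + (1 − w₁)·N(µ₂, σ₂²) by EM. Defaults: convergence
when the log-likelihood improves by < 1e-8, at most 500 iterations, best of
5 starts. The first start is deterministic — component moments from a
split at the sample median — so a single-start fit is reproducible without
a seed; the remaining starts draw random responsibilities. A variance
floor σ ≥ 1e-3 (log2 units) keeps the likelihood bounded away from the
single-point singularity. Components are reported with µ₁ ≤ µ₂, and the
per-iteration log-likelihood path is retained so the EM ascent property is
testable on every fit.

The bimodal score is |µ₁ − µ₂| / max(σ₁, σ₂) — a separation-to-spread
ratio, a rough analog of a t-statistic — and is invariant under positive
affine transforms of the data, as is the dip. A weight-balance criterion
|w₁ − w₂| < 0.25 (strict inequality; boundary fits fail) requires both
expression states to hold comparable cohort fractions.

On truly single-normal data the two-component MLE does not collapse to
coincident components at finite n: the best-of-starts fit typically shaves
off a small tail component. Calibrated null scores: median ~0.65
(max ~1.6) at n = 1000, median ~1.4 (max ~4) at n = 112. Most high-score
null fits are weight-unbalanced — the weight criterion removes ~86% of
null fits with score > 2 at n = 112 — which is the practical reason the
criterion exists.

Ranking: genes with dip p < α_dip *and* a balanced fit are ordered by
descending score (ties broken lexicographically by gene id) and the top
`top_k` (default 200) are kept. The weight criterion is applied before
ranking, as an eligibility filter. A configurable pre-filter excludes genes
with > 20% of samples tied at the minimum value (detection-floor point
masses break the mixture model); it can be disabled.

## Survival screening

Each ranked gene is dichotomized at its median (high iff value strictly
above; ties go low, which is deterministic and conservative for the
high-risk call). Group survival is compared by the two-group log-rank test
and by a Cox proportional-hazards fit of the binary indicator
(low = reference; lifelines, Efron tie handling), reporting HR, 95% Wald
CI, Wald p, log-rank p and Harrell's concordance. HR > 1 labels the
high-expression state poor-prognosis. A gene is *survival-significant*
when its log-rank p < α (default 0.05); the choice of the log-rank p as
the gate (rather than the Cox Wald p, which is asymptotically equivalent
for a binary covariate) is configurable, and Benjamini–Hochberg adjusted
log-rank p-values are reported alongside without being used as a gate.
Significant genes are re-tested with a multivariate Cox model adding age
(years, continuous), tumor stage (binary advanced III/IV vs localized
I/II; an ordinal encoding is available) and gender; samples with missing
stage are dropped from the adjusted model only, with the count logged.
*Robust* means adjusted gene-term p < α. Degenerate fits (no events,
complete separation, non-convergence) yield flagged non-estimable results
rather than exceptions.

## Partition and pathway score

Survival-significant genes are split by |Pearson r| against a reference
proliferation marker (MKI67 by default): |r| < 0.3 is "low-correlated",
i.e. a candidate biomarker complementary to proliferation-based prognosis.
The threshold is exposed and the full r table is always emitted so any
cut can be audited. The pathway score of a gene set is the per-sample
unweighted mean of log2(FPKM + 1) over the members (no z-scoring); it is
median-split and screened exactly like a single gene. The default set is
the semaphorin–integrin axis SEMA7A, ITGB1, AKT1, PTK2, MAPK1, LIMK1,
CFL1 (protein aliases mapped to symbols: AKT → AKT1, PTK/FAK → PTK2,
ERK → MAPK1); any one-symbol-per-line file can replace it.

## Batch correction and orchestration

Batch effects are removed per gene by subtracting additive batch means and
restoring the grand mean — regressing out a batch indicator with no other
covariates. An exactly additive shift is removed to machine precision;
bimodal structure orthogonal to batch is preserved. Sample-id matching
between expression and clinical tables is strict (mismatch is an error;
intersect upstream deliberately, not silently). One pipeline seed drives
the dip null simulation and EM restarts through spawned child generators,
so reruns are byte-identical and stages are individually reproducible; the
stagewise functions compose to the same result as the one-call pipeline.

## Synthetic cohorts

The generator inverts the model the screen assumes. Defaults mirror a
rare-tumor two-source cohort: 112 samples in two batches of 79 + 33,
~2000 genes (a compute-friendly subsample of a transcriptome; the method
is per-gene, so gene count only scales runtime and multiplicity), planted
bimodal genes drawn from N(2, 1)/N(6, 1) with w₁ = 0.5 (true score 4),
unimodal background N(4, 1). Survival is exponential with baseline hazard
ln 2 / 43 per month — median overall survival 43 months in the reference
group — multiplied by exp(log HR) for high-component samples, default
log HR = log 4.27. Censoring is administrative: uniform on [0, T_max] with
T_max solved by root-finding so the expected censored fraction matches the
target (default 0.67, i.e. ~33% observed deaths). Covariates: age
N(47, 12²), advanced-stage prevalence 0.43, female fraction 0.69,
hormone-producing fraction 0.65; optional age/stage log-hazard effects
default to zero.

By default all prognostic genes share one latent component membership — a
two-subtype cohort in which the same patient subpopulation expresses the
high state of every prognostic gene and carries the elevated hazard, the
scenario the method targets. With `shared_membership=False` each planted
gene draws independent memberships and per-gene log hazard ratios add.

What the generator does *not* emulate: count-level noise (negative
binomial), library-size and gene-length effects, correlated background
genes, non-proportional hazards, informative censoring. Passing tests
therefore show the pipeline recovers its own generative model at the
study's scale — parameter recovery, calibration and ranking behavior —
not that real cohorts satisfy that model.

## Problem sizes used in tests and acceptance runs

Unit tests use 112-sample cohorts of 150–1000 genes. The acceptance
experiments use: 100 random samples (n ≤ 50) for the dip/reference
agreement; 2000 uniform replicates at n = 112 (20 rotating B = 2000 null
tables) for calibration; 200 replicates for EM recovery and for Cox
HR/CI-coverage recovery at n = 112 with ~33% deaths; a 2000-gene cohort
with 50 planted score-4 genes for screening recall; and a 600-gene cohort
with 260 non-prognostic bimodal genes for the null survival screen of 200
ranked genes.

## Known limitations

- The dip gate's power, not the mixture fit, limits sensitivity; genes
  with separation below ~4·σ are mostly invisible at n ≈ 112.
- The Monte-Carlo dip p-value is conservative for non-uniform unimodal
  expression distributions.
- Median dichotomization discards within-group dose information by design
  (the method's choice, kept here).
- The multivariate model assumes proportional hazards and linear age
  effects; no diagnostics are provided.
- With heavy ties at the median (> half the samples at one value) the
  split is degenerate and the gene is reported non-estimable.
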