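# Methods

This note documents the models, numerical choices and known limitations of
`diabclust`. It is written for users who need to judge what the pipeline's
outputs do and do not establish.

## The clustering procedure

The subtype assignment is a faithful implementation of the GADA-gated,
sex-stratified k-means protocol for adult diabetes:

1. **SAID gate.** GADA ≥ 5 U/ml (threshold inclusive) ⇒ SAID; these patients
   never enter k-means. Patients with no GADA measurement are by default
   still clustered (`include_gada_unknown=True`), flagged by provenance;
   a switch restricts clustering to confirmed negatives.
2. **Scaling.** The five features (HbA1c %, BMI kg/m², age at onset years,
   HOMA2-B %, HOMA2-IR) are z-scored with the *sample* SD (ddof = 1), within
   duration-stratum × sex by default (`scale_within_sex`); a pooled-scaling
   switch exists. The choice matters little when sex differences are small
   but keeps each k-means self-contained.
3. **k-means.** k = 4, Lloyd iterations (max 100), Euclidean distance,
   100 restarts, the restart with the highest average silhouette width (ASW)
   wins. Restarts are seeded by k-means++. We prototyped a Hartigan–Wong
   refinement stage and rejected it: deeper SSE optimisation systematically
   found partitions with *lower* ASW, i.e. it fights the selection criterion.
   Runs that collapse below 4 non-empty clusters are discarded and redrawn;
   ASW ties keep the earliest run. Everything is deterministic under
   `random_state` (one `SeedSequence`, one child per sex).
4. **Merging.** Male and female solutions are merged by the exhaustive
   minimum-cost bijection (4! = 24 pairings) between scaled centroids. The
   published protocol says only that sex-specific results were "merged
   afterward"; centroid matching is this package's construction.
5. **Archetype naming.** Merged clusters are scored against fixed signature
   directions in z-space — SIDD: (HbA1c +1, HOMA2-B −1); SIRD: (HOMA2-IR +1,
   BMI +0.5); MOD: (BMI +1); MARD: (age at onset +1, HbA1c −0.5) — and the
   cost-minimising bijection (negative dot product, exhaustive, lexicographic
   tie-break) assigns names. In the long-term stratum the SIRD- and MOD-slot
   clusters are renamed IROD1/IROD2 in ascending order of raw HOMA2-B,
   matching their published definitions (IROD1: high insulin resistance with
   reduced β-cell function; IROD2: preserved, markedly elevated HOMA2-B).
   Naming is deterministic and invariant to cluster index permutations.

k selection is deliberately absent (the protocol fixes k = 4; the `krange`
of the original call has a single element) and all features carry equal
weight — a known limitation of the approach that is reproduced, not
improved.

## Clinical indices

* **eGFR**: 4-variable MDRD, `186 · (creatinine/88.4)^−1.154 · age^−0.203`,
  × 0.742 for women. Creatinine in µmol/L. Only this equation is
  implemented; CKD-EPI is out of scope.
* **HOMA2**: the canonical HOMA2 indices come from an external, closed-source
  iterative calculator. That model is *not* reimplemented. The package
  (a) passes through supplied HOMA2 columns unchanged, which is the default
  data path and the one the synthetic generator uses, and (b) offers a
  transparent surrogate for raw-input mode: an insulin-equivalent
  `I = k·CP` (k = 7.5, calibrated so cohort-scale C-peptide values yield
  cohort-scale indices) with `B = 20·I/(G−3.5)` and `IR = I·G/22.5`.
  Glucose outside the calculator's documented domain [3.5, 25] mmol/L is
  clamped high with a per-row flag; at or below 3.5 the indices are flagged
  missing rather than raising. No pipeline result depends on the surrogate.

## Phenotyping rules

Composite complications are ORs of component flags (PDR: proliferative
retinopathy / laser treatment / blindness; CKD: eGFR < 60 strictly /
nephropathy / dialysis / ESRD; CVD: MI / stroke). Missing components count
as absent — complication status comes from discharge records, where absence
of a record is absence of a diagnosis — with per-component missingness
reported. Eligibility: age at onset strictly over 18; complete clustering
features, sex, duration; then a *single-pass* 3-SD screen on BMI, HOMA2-B
and HOMA2-IR with mean/SD estimated once from the completeness-filtered pool
(a config switch screens within stratum instead). Exclusions are attributed
to the first failing rule (age → completeness → 3-SD) in a ledger whose
counts always reconcile with the input size. Note the screen is not exactly
idempotent: re-applying it re-estimates the bounds on a slightly tighter
pool and can remove a further ≲1% of records. Duration exactly 3 years goes
to the long-term stratum (the published strata, "less than" / "more than" 3
years, leave the boundary point unassigned; one convention is fixed here).

## The synthetic cohort generator

The generator is the package's substitute for the non-distributable study
data: every published quantity enters as a generating parameter, and the
pipeline is validated by recovering it.

* **Structure.** Two strata (new-onset n = 887, long-term n = 1,253 by
  default), five clusters each with the published frequencies (new-onset
  6/14/27/7/46%; long-term 11/25/20/17/27% — the IROD1/IROD2 split is not
  printed numerically and was fixed at 20/17 to close the stratum).
* **Features** are drawn independently within cluster from truncated normals
  (bounds: BMI [15, 60], HbA1c [4, 18], HOMA2-B [1, 400], HOMA2-IR
  [0.1, 10], age at onset [18, 95]). The published per-cluster means/SDs
  (SIRD HOMA2-IR 3.4 ± 1.1, HOMA2-B 121.7 ± 42.2; MOD BMI 34.0 ± 4.9, …;
  IROD1 65.7 ± 27.8; IROD2 139.4 ± 38.8, BMI 32.0 ± 4.5; MARD age ≈ 59.8 ±
  11.7) are used verbatim. Unprinted means/SDs were calibrated once, under
  two constraints: qualitative fidelity to the published cluster
  descriptions, and pairwise scaled-centroid separation ≥ 2 pooled SDs among
  the k-means clusters — the regime in which k-means recovery of a mixture
  is attainable at all. This calibration trades away exact reproduction of
  the stratum-level marginal means (the mixture-averaged HOMA2-B/IR sit
  10–15% below the published stratum marginals); both could not hold at once
  given the published within-cluster SDs.
* **GADA** is log-normal, truncated below the 5 U/ml threshold for non-SAID
  clusters and shifted above it for SAID, so positivity coincides exactly
  with the generating SAID label.
* **Durations**: Uniform(0, 3) years for new-onset; 3 + Gamma matched to
  mean 11, SD 6.9 for long-term. Age at visit = age at onset + duration.
* **Complications** are Bernoulli draws from per-complication logistic models
  (intercept = MARD baseline at the covariate centring point; cluster
  log-ORs from the published long-term odds ratios, e.g. SAID-PDR log 9.32;
  age 0.02/yr, male +0.15, duration 0.04/yr). Baselines were set so overall
  prevalences approximate the published stratum prevalences. Creatinine is
  drawn consistently with the drawn CKD outcome (non-CKD patients never have
  eGFR < 60; CKD patients carry either elevated creatinine or a
  documented-nephropathy flag), so re-deriving the phenotype reproduces the
  configured model.
* **Genotypes**: per SNP, dosage ~ Binomial(2, f_cluster) with
  logit(f_cluster) = logit(RAF) + cluster log-OR, i.e. Hardy–Weinberg within
  cluster and an exactly additive logistic model for the IROD2 contrast.
  The published RAF is the frequency of the comparison clusters; under a
  protective IROD2 effect the pooled frequency sits slightly below it.
* **What it does not emulate**: within-cluster feature correlations (none
  are published; features are independent given the cluster), treatment
  trajectories (e.g. sulfonylurea-induced HOMA2-B decline), assay error,
  genotyping/imputation artefacts, and any real-data cluster-boundary
  geometry. Passing recovery tests therefore demonstrates correctness of
  the machinery under the stated generative model, not performance of the
  protocol on real cohorts.

## Statistical models

Complication risks: maximum-likelihood logistic regression (statsmodels),
cluster indicators with MARD reference, adjusted for age, sex (male = 1;
cluster ORs are invariant to this coding, asserted by test) and duration.
Wald 95% CIs (`exp(β ± 1.96·SE)`); non-convergence and separation are
flagged, never dropped. FDR is Benjamini–Hochberg over all cluster ×
complication tests within a duration stratum. New-onset outcomes with fewer
than 5 events (in practice PDR) are skipped, mirroring the published
analysis. Genetic contrasts: outcome IROD2 vs comparison group (all other
non-SAID long-term clusters, or a single cluster), predictor additive
dosage, adjusted for sex and age; SAID is always excluded; Bonferroni m =
number of SNPs actually tested. MAF/missingness pre-filters exist but
default to off.

## Recovery behaviour and known biases

Labeled-cluster summaries are *outputs of the partition*, not unbiased
estimates of generating parameters. Two structural effects are documented:

* the labeled SIRD mean HOMA2-IR runs ≈ +0.1–0.3 above the generating 3.4
  at n = 2,000: the ASW-selected partition shaves SIRD's low-IR boundary.
  The generating partition is not even a Lloyd fixed point on such
  realisations, so no restart schedule can return it exactly;
* the labeled long-term SIDD share runs ≈ +2 points above the generating
  25%: the young, high-HbA1c tail of the (very age-dispersed) MARD cluster
  is absorbed by SIDD.

Both effects are inherent to k-means on overlapping mixtures with the
published within-cluster SDs and would equally affect the original protocol.

## Numerical conventions

Silhouette: `s_i = (b_i − a_i)/max(a_i, b_i)`, singletons and 0/0 cases
scored 0; one pairwise-distance matrix is shared across all 100 restarts for
n ≤ 5,000. Scaling uses ddof = 1 throughout. Matching and naming bijections
are exhaustive (k! = 24), with deterministic tie-breaks (first-found /
lexicographic). All randomness flows from a single integer seed through
`numpy` `SeedSequence` spawning; per-run k-means seeds are reduced modulo
2³¹−1. Problem sizes in the shipped recovery benchmarks (2,000 per stratum
for centroid checks; 20,000 for complication-OR refits; 10,000 for SNP
refits) were chosen to keep each target's Monte-Carlo error well inside its
comparison band while completing in seconds.
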