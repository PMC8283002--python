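# diabclust

Pathophysiology-based reclassification of adult diabetes, as a tested Python
pipeline. Adult diabetes is clinically heterogeneous: the same "type 2" label
covers autoimmune β-cell loss, severe insulin deficiency, severe insulin
resistance, obesity-driven disease and mild age-related disease, with very
different complication risks. `diabclust` implements the five-cluster
reclassification — SAID, SIDD, SIRD, MOD, MARD, plus the
long-term-disease variants IROD1/IROD2 — together with everything needed to
study it end to end without patient-level data: a synthetic cohort generator
with retained ground truth, clinical index computation, complication
phenotyping, cluster-wise complication risk models, and per-SNP genetic
association of the IROD2 cluster.

It is written for biostatisticians and epidemiologists who want to replicate,
stress-test or extend the clustering protocol.

## The method

**Gating and clustering.** GADA-positive patients (glutamic acid decarboxylase
autoantibodies ≥ 5 U/ml) form the **SAID** cluster directly. The remainder are
clustered by k-means (k = 4, Euclidean, Lloyd iterations) on five centred and
scaled features

> HbA1c, BMI, age at diabetes onset, HOMA2-B, HOMA2-IR

separately for men and women (to avoid sex bias), in two duration strata
(new-onset < 3 years, long-term ≥ 3 years). Each k-means is restarted 100
times and the partition with the highest **average silhouette width** (ASW) is
kept; the male and female solutions are merged by the minimum-cost bijection
between their scaled centroids, and the merged clusters are named **SIDD**
(high HbA1c, low HOMA2-B), **SIRD** (high HOMA2-IR, elevated BMI), **MOD**
(high BMI) and **MARD** (high age at onset) by a cost-minimising bijection
against fixed signature directions in z-space. In long-term disease the two
insulin-resistant obese clusters are renamed **IROD1** (lower HOMA2-B) and
**IROD2** (markedly elevated HOMA2-B).

**Clinical indices.** eGFR uses the 4-variable MDRD equation,
`186 · (creatinine/88.4)^−1.154 · age^−0.203 (· 0.742 if female)`; chronic
kidney disease is eGFR < 60 mL/min/1.73 m², documented nephropathy, dialysis
or ESRD; proliferative retinopathy is proliferative retinopathy, laser
treatment or blindness; CVD is myocardial infarction or stroke. HOMA2 indices
are normally supplied (or simulated) directly; a documented surrogate backend
(`B = 20·k·CP/(G−3.5)`, `IR = k·CP·G/22.5`, k = 7.5) maps C-peptide and
fasting glucose to the HOMA2 scales when only raw measurements exist.

**Risk and genetics.** Complication risks per cluster are odds ratios from
logistic regression versus the MARD reference, adjusted for age, sex and
diabetes duration, with Benjamini–Hochberg FDR within each duration stratum.
Genetic analysis contrasts IROD2 against the other long-term clusters (SAID
excluded) per SNP, with additive risk-allele dosage adjusted for sex and age
and Bonferroni correction; the eight-SNP type-2-diabetes panel
(`src/diabclust/data/snp_panel.tsv`) ships with the package.

**Synthetic cohorts.** `CohortConfig` specifies stratum sizes, cluster
proportions, per-cluster truncated-normal feature distributions, the logistic
complication models and the per-SNP allele-frequency models. The shipped
defaults encode the published cohort structure (e.g. new-onset frequencies
SAID 6%, SIDD 14%, SIRD 27%, MOD 7%, MARD 46%; SIRD HOMA2-IR 3.4 ± 1.1; IROD2
HOMA2-B 139.4 ± 38.8; SAID-vs-MARD PDR OR 9.32). Generation is fully
deterministic under the config seed.

## Worked example

Run the whole pipeline on a synthetic cohort of the study's size
(887 new-onset + 1,253 long-term patients):

```bash
diabclust --quiet run-all --seed 1 --out out/
cat out/cluster_frequencies.tsv
```

```
stratum     cluster_label  n    pct
new_onset   MARD           406  46.29
new_onset   SIRD           224  25.54
new_onset   SIDD           118  13.45
new_onset   MOD            80   9.12
new_onset   SAID           49   5.59
long_term   MARD           329  27.01
long_term   SIDD           316  25.94
long_term   IROD1          246  20.20
long_term   IROD2          173  14.20
long_term   SAID           154  12.64
```

The pipeline-recovered frequencies sit close to the generating proportions
(new-onset MARD 46%, long-term SIDD 25%, ...): the clustering gives back the
structure the generator put in. The long-term risk table reproduces the
elevated PDR risk of the autoimmune cluster:

```
grep "^pdr" out/risks_long_term.tsv  # outcome cluster or ci_low ci_high p q ...
pdr  SAID   11.51  3.91  33.88  9.2e-06  7.4e-05 ...
```

i.e. SAID patients carry an ~11-fold adjusted odds of proliferative
retinopathy versus MARD (simulated truth: 9.32). Other outputs:
per-patient assignments with silhouette values, per-cluster centroid tables,
descriptive summaries, SNP association tables, an exclusion ledger and a
manifest with checksums (`manifest.json`) — rerunning with the same seed
reproduces every file byte-identically.

The same steps are available as a library:

```python
from diabclust import default_config, generate_cohort, DiabetesSubtypeClustering

syn = generate_cohort(default_config(seed=1))
est = DiabetesSubtypeClustering(stratum="long_term", random_state=1)
labels = est.fit_predict(syn.cohort.df[syn.cohort.df.duration >= 3])
est.result_.centroids          # raw-scale centroids per final label
```

`DiabetesSubtypeClustering` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit`/`fit_predict`, fitted attributes `labels_`,
`result_`, `asw_`).

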