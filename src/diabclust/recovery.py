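"""Parameter-recovery benchmarks: regenerate a cohort from the shipped defaults
and measure how well the pipeline recovers the configured quantities.

These helpers exist because the study cohort itself is not distributable: the
published frequencies, centroids and odds ratios enter the generator as truth,
and the pipeline's job is to give them back.  Each function runs the relevant
slice of the pipeline from scratch at a stated size and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .clustering import run_clustering_pipeline
from .config import default_config
from .genetics import fit_snp_model
from .phenotyping import apply_inclusion_filters, derive_complications, split_duration
from .risk import fit_complication_model
from .simulate import generate_cohort

Z975 = 1.959963984540054


@dataclass
class ClusterRecovery:
    """Labeled-cluster summaries from one full pipeline run on one stratum."""

    stratum: str
    n: int
    label_pct: Dict[str, float]  # % of the labeled cohort per final label
    label_means: pd.DataFrame  # raw-scale feature means per final label
    label_counts: Dict[str, int]
    label_sds: pd.DataFrame


def run_cluster_recovery(
    stratum: str, n: int, seed: int, runs: int = 100
) -> ClusterRecovery:
    """Generate a single-stratum cohort from the shipped defaults, phenotype,
    filter and cluster it, and summarize the labeled clusters."""
    sizes = {"new_onset": 1, "long_term": 1}
    sizes[stratum] = n
    cfg = default_config(
        seed=seed, n_new_onset=sizes["new_onset"], n_long_term=sizes["long_term"]
    )
    syn = generate_cohort(cfg)
    df = derive_complications(syn.cohort.df)
    df, _ = apply_inclusion_filters(df)
    new_onset, long_term = split_duration(df)
    part = new_onset if stratum == "new_onset" else long_term
    res = run_clustering_pipeline(part, stratum, runs=runs, seed=seed)
    merged = part.reset_index(drop=True).join(
        res.assignments[["cluster_label"]]
    )
    feats = ["hba1c", "bmi", "age_at_onset", "homa2_b", "homa2_ir"]
    by = merged.groupby("cluster_label")
    return ClusterRecovery(
        stratum=stratum,
        n=len(merged),
        label_pct={k: 100.0 * v / len(merged) for k, v in by.size().items()},
        label_means=by[feats].mean(),
        label_counts=by.size().to_dict(),
        label_sds=by[feats].std(ddof=1),
    )


@dataclass
class OrRecovery:
    or_hat: float
    se_log: float
    n: int

    @property
    def log_or(self) -> float:
        return math.log(self.or_hat)


def recover_complication_or(
    outcome: str, cluster: str, seed: int, n: int = 20000
) -> OrRecovery:
    """Simulate a long-term cohort at size ``n`` and refit the adjusted
    MARD-reference logistic model for one complication; return the cluster OR."""
    cfg = default_config(seed=seed, n_new_onset=1, n_long_term=n)
    syn = generate_cohort(cfg)
    df = syn.cohort.df.merge(syn.truth, on="patient_id")
    df = df[df["stratum"] == "long_term"].rename(
        columns={"truth_cluster": "cluster_label"}
    )
    df = derive_complications(df)
    res = fit_complication_model(df, outcome)
    r = next(x for x in res if x.predictor == cluster)
    se = (math.log(r.ci_high) - math.log(r.ci_low)) / (2 * Z975)
    return OrRecovery(or_hat=r.or_hat, se_log=se, n=len(df))


def recover_snp_or(rsid: str, seed: int, n: int = 10000) -> OrRecovery:
    """Simulate long-term genotypes and refit the sex- and age-adjusted
    IROD2-versus-all model for one SNP."""
    cfg = default_config(seed=seed, n_new_onset=1, n_long_term=n)
    syn = generate_cohort(cfg, with_genotypes=True)
    ass = syn.cohort.df.merge(syn.truth, on="patient_id")
    ass = ass[ass["stratum"] == "long_term"].rename(
        columns={"truth_cluster": "cluster_label"}
    )
    r = fit_snp_model(ass, syn.genotypes.dosages[rsid], rsid=rsid)
    se = (math.log(r.ci_high) - math.log(r.ci_low)) / (2 * Z975)
    return OrRecovery(or_hat=r.or_hat, se_log=se, n=r.n_cases + r.n_controls)
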