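"""Per-SNP association of IROD2 membership with additive risk-allele dosage.

Long-term stratum only, SAID excluded.  For each SNP a logistic regression of
IROD2 membership (1) versus a comparison group (0: all other non-SAID clusters
by default, or a single named cluster) on the additive dosage, adjusted for
sex and age.  Bonferroni correction over the number of SNPs tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import GenotypeMatrix

Z975 = 1.959963984540054

CONTRASTS = ("IROD2_vs_all", "IROD2_vs_IROD1", "IROD2_vs_SIDD", "IROD2_vs_MARD")


@dataclass
class SnpAssociation:
    rsid: str
    gene: str
    risk_allele: str
    raf: float
    contrast: str
    or_hat: float
    ci_low: float
    ci_high: float
    p: float
    p_bonferroni: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    skipped: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "rsid": self.rsid, "gene": self.gene, "risk_allele": self.risk_allele,
            "raf": self.raf, "contrast": self.contrast, "or": self.or_hat,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
            "p_bonferroni": self.p_bonferroni, "n_cases": self.n_cases,
            "n_controls": self.n_controls, "skipped": self.skipped or "",
        }


def compute_raf(dosages: Sequence[float]) -> float:
    """Pooled risk-allele frequency: sum(dosage) / (2 * n non-missing)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("all dosages missing")
    return float(d.sum() / (2 * len(d)))


def bonferroni(pvalues: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """min(1, p * m); m defaults to the number of tests supplied."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p) if m is None else m
    if m < 1 or m < len(p):
        raise ValueError(f"invalid Bonferroni m={m} for {len(p)} tests")
    return np.minimum(1.0, p * m)


def fit_snp_model(
    assignments: pd.DataFrame,
    dosage: pd.Series,
    contrast: str = "IROD2_vs_all",
    rsid: str = "",
    gene: str = "",
    risk_allele: str = "",
    covariates: Sequence[str] = ("sex", "age"),
) -> SnpAssociation:
    """Fit one SNP's IROD2 contrast, sex- and age-adjusted.

    ``assignments`` needs patient_id, cluster_label, sex, age (long-term
    stratum); ``dosage`` is indexed by patient_id.  SAID rows are always
    excluded.  A monomorphic SNP in the analysis sample is skipped with reason.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    df = assignments[assignments["cluster_label"] != "SAID"].copy()
    if contrast != "IROD2_vs_all":
        other = contrast.split("_vs_")[1]
        df = df[df["cluster_label"].isin(["IROD2", other])]
    df = df.set_index("patient_id")
    d = dosage.reindex(df.index).astype(float)
    keep = d.notna()
    df, d = df[keep], d[keep]
    y = (df["cluster_label"] == "IROD2").astype(float).to_numpy()
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    raf = compute_raf(d.to_numpy()) if len(d) else np.nan
    base = dict(rsid=rsid, gene=gene, risk_allele=risk_allele, raf=raf,
                contrast=contrast, n_cases=n_cases, n_controls=n_controls)
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"{contrast}: empty contrast group")
    if d.nunique() < 2:
        return SnpAssociation(**base, or_hat=np.nan, ci_low=np.nan,
                              ci_high=np.nan, p=np.nan, skipped="monomorphic")
    Xcols = {"dosage": d.to_numpy()}
    for cov in covariates:
        Xcols[cov] = ((df["sex"] == "male").astype(float) if cov == "sex"
                      else df[cov].astype(float)).to_numpy()
    X = sm.add_constant(pd.DataFrame(Xcols), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return SnpAssociation(**base, or_hat=np.nan, ci_low=np.nan,
                              ci_high=np.nan, p=np.nan, skipped="separation")
    beta, se = fit.params["dosage"], fit.bse["dosage"]
    return SnpAssociation(
        **base,
        or_hat=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=float(fit.pvalues["dosage"]),
    )


def run_genetics(
    assignments: pd.DataFrame,
    genotypes: GenotypeMatrix,
    contrasts: Sequence[str] = ("IROD2_vs_all",),
    panel_meta: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """All SNPs x contrasts; Bonferroni within contrast over SNPs tested."""
    meta = genotypes.snps.set_index("rsid")
    gene_of = {}
    if panel_meta is not None and "gene" in panel_meta.columns:
        gene_of = panel_meta.set_index("rsid")["gene"].to_dict()
    results: List[SnpAssociation] = []
    for contrast in contrasts:
        batch = []
        for rsid in genotypes.dosages.columns:
            res = fit_snp_model(
                assignments, genotypes.dosages[rsid], contrast=contrast,
                rsid=rsid, gene=gene_of.get(rsid, ""),
                risk_allele=str(meta.loc[rsid, "risk_allele"]),
            )
            batch.append(res)
        tested = [r for r in batch if r.skipped is None]
        if tested:
            adj = bonferroni([r.p for r in tested], m=len(tested))
            for r, pb in zip(tested, adj):
                r.p_bonferroni = float(pb)
        results.extend(batch)
    return pd.DataFrame([r.to_dict() for r in results])
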