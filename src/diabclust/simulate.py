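"""Synthetic cohort generator with retained ground truth.

Generates patient-level cohorts with the mixture structure the downstream
analysis assumes: per duration stratum, cluster labels are drawn from the
configured proportions; the five clustering features are drawn independently
within cluster from truncated normals; GADA concentrations are drawn so that
positivity coincides exactly with the generating SAID label; complications are
Bernoulli draws from per-complication logistic models in cluster, age, sex and
duration; SNP dosages are Binomial(2, f_c) with cluster-dependent risk-allele
frequencies (Hardy-Weinberg within cluster by construction).

Everything is driven by one :class:`numpy.random.Generator`, so a config (whose
``seed`` field is part of the config) regenerates the identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CLUSTER_FEATURES,
    GADA_THRESHOLD,
    TRUNCATION_BOUNDS,
    CohortConfig,
    SnpSpec,
    StratumConfig,
)
from .io import CohortTable, GenotypeMatrix


@dataclass
class SyntheticCohort:
    """A generated cohort: canonical table, per-patient truth labels, genotypes."""

    cohort: CohortTable
    truth: pd.DataFrame  # patient_id, stratum, truth_cluster
    genotypes: Optional[GenotypeMatrix]
    config: CohortConfig


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _gada(rng: np.random.Generator, positive: bool, mu: float, sigma: float,
          size: int) -> np.ndarray:
    if positive:
        return GADA_THRESHOLD + rng.lognormal(mu, sigma, size=size)
    # log-normal truncated above at the threshold via inverse-CDF sampling
    cap = stats.lognorm.cdf(GADA_THRESHOLD, s=sigma, scale=np.exp(mu))
    u = rng.uniform(0.0, cap, size=size)
    return stats.lognorm.ppf(u, s=sigma, scale=np.exp(mu))


def _durations(rng: np.random.Generator, spec: StratumConfig, size: int) -> np.ndarray:
    d = spec.duration
    if d.kind == "uniform":
        return rng.uniform(d.low, d.high, size=size)
    shape, scale = d.gamma_shape_scale()
    return d.shift + rng.gamma(shape, scale, size=size)


def _creatinine_given_ckd(rng: np.random.Generator, ckd: np.ndarray,
                          age: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Creatinine consistent with the drawn CKD outcome.

    Non-CKD rows draw creatinine below the per-person eGFR=60 threshold so the
    eGFR component never contradicts the configured outcome; CKD rows either
    carry elevated creatinine (eGFR < 60) or a documented-nephropathy flag.
    """
    sex_f = 186.0 * np.where(sex == "female", 0.742, 1.0) * age**-0.203
    # creatinine (umol/L) at which MDRD eGFR equals 60 for this person
    thresh = 88.4 * (60.0 / sex_f) ** (-1.0 / 1.154)
    n = len(ckd)
    creat = np.empty(n)
    nephro = np.zeros(n, dtype=bool)
    low = _truncnorm(rng, 75.0, 14.0, 40.0, 1e9, n)
    low = np.minimum(low, thresh * 0.97)
    via_egfr = rng.uniform(size=n) < 0.5
    high = thresh * rng.uniform(1.05, 1.8, size=n)
    creat = np.where(ckd & via_egfr, high, low)
    nephro = ckd & ~via_egfr
    return creat, nephro


def _complication(rng: np.random.Generator, model, labels: np.ndarray,
                  age: np.ndarray, sex: np.ndarray, duration: np.ndarray) -> np.ndarray:
    eta = np.full(len(labels), model.intercept)
    for cluster, beta in model.cluster_log_or.items():
        eta += beta * (labels == cluster)
    eta += model.age_coef * (age - model.age_center)
    eta += model.sex_coef * (sex == "male")
    eta += model.duration_coef * (duration - model.duration_center)
    p = 1.0 / (1.0 + np.exp(-eta))
    return rng.uniform(size=len(labels)) < p


def generate_stratum(rng: np.random.Generator, name: str, spec: StratumConfig,
                     id_offset: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels_order = spec.labels
    props = np.array([spec.clusters[c].proportion for c in labels_order])
    labels = rng.choice(labels_order, size=spec.n, p=props / props.sum())

    df = pd.DataFrame({
        "patient_id": [f"P{id_offset + i:06d}" for i in range(spec.n)],
        "sex": np.where(rng.uniform(size=spec.n) < spec.male_fraction, "male", "female"),
    })
    for feat in CLUSTER_FEATURES:
        lo, hi = TRUNCATION_BOUNDS[feat]
        vals = np.empty(spec.n)
        for cluster in labels_order:
            mask = labels == cluster
            d = spec.clusters[cluster].features[feat]
            vals[mask] = _truncnorm(rng, d.mean, d.sd, lo, hi, int(mask.sum()))
        df[feat] = vals
    df["duration"] = _durations(rng, spec, spec.n)
    df["age"] = df["age_at_onset"] + df["duration"]
    gada = np.empty(spec.n)
    for cluster in labels_order:
        mask = labels == cluster
        g = spec.clusters[cluster].gada
        gada[mask] = _gada(rng, g.positive, g.mu, g.sigma, int(mask.sum()))
    df["gada"] = gada
    waist_offset = np.zeros(spec.n)
    for cluster in labels_order:
        waist_offset[labels == cluster] = spec.clusters[cluster].waist_offset
    df["waist"] = 2.55 * df["bmi"] + 19.0 + waist_offset + rng.normal(0, 6, size=spec.n)
    df["fasting_glucose"] = np.clip(
        0.8 * df["hba1c"] + 1.0 + rng.normal(0, 1.0, size=spec.n), 3.9, 25.0
    )
    df["c_peptide"] = _truncnorm(rng, 0.9, 0.5, 0.05, 3.0, spec.n)

    age = df["age"].to_numpy()
    sex = df["sex"].to_numpy()
    dur = df["duration"].to_numpy()
    outcomes = {
        comp: _complication(rng, model, labels, age, sex, dur)
        for comp, model in spec.complications.items()
    }
    creat, nephro = _creatinine_given_ckd(rng, outcomes["ckd"], age, sex)
    df["creatinine"] = creat
    df["proliferative_retinopathy"] = outcomes["pdr"]
    df["laser_treatment"] = False
    df["blindness"] = False
    df["documented_nephropathy"] = nephro
    df["dialysis"] = False
    df["esrd"] = False
    df["peripheral_neuropathy"] = outcomes["neuropathy"]
    mi_split = rng.uniform(size=spec.n) < 0.6
    df["mi"] = outcomes["cvd"] & mi_split
    df["stroke"] = outcomes["cvd"] & ~mi_split
    df["insulin_treatment"] = rng.uniform(size=spec.n) < np.where(
        np.isin(labels, ["SAID", "SIDD"]), 0.5, 0.1
    )
    truth = pd.DataFrame({
        "patient_id": df["patient_id"],
        "stratum": name,
        "truth_cluster": labels,
    })
    return df, truth


def generate_cohort(config: CohortConfig, with_genotypes: bool = False) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``config``."""
    rng = np.random.default_rng(config.seed)
    frames, truths, offset = [], [], 0
    for name in ("new_onset", "long_term"):
        if name not in config.strata:
            continue
        df, truth = generate_stratum(rng, name, config.strata[name], id_offset=offset)
        offset += len(df)
        frames.append(df)
        truths.append(truth)
    df = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    cohort = CohortTable(df=df, source="synthetic")
    syn = SyntheticCohort(cohort=cohort, truth=truth, genotypes=None, config=config)
    if with_genotypes and config.snps:
        syn.genotypes = generate_genotypes(syn, config.snps, rng)
    return syn


def generate_genotypes(
    cohort: SyntheticCohort,
    panel: list[SnpSpec],
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Draw additive dosages Binomial(2, f_cluster) for each SNP in the panel."""
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    truth = cohort.truth
    dos = {}
    for snp in panel:
        freqs = np.array([snp.cluster_freq(c) for c in truth["truth_cluster"]])
        dos[snp.rsid] = rng.binomial(2, freqs).astype(float)
    dosages = pd.DataFrame(dos, index=pd.Index(truth["patient_id"], name="sample_id"))
    snps = pd.DataFrame(
        [
            {"rsid": s.rsid, "chrom": s.chrom, "pos": s.bp,
             "risk_allele": s.risk_allele, "other_allele": s.other_allele}
            for s in panel
        ]
    )
    return GenotypeMatrix(snps=snps, dosages=dosages)
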