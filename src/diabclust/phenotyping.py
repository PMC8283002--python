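"""Eligibility filtering, composite complication phenotypes, GADA status, strata.

Inclusion rules follow the study design for adult diabetes: age at diagnosis
strictly above 18 years, complete information on the five clustering features
plus sex, duration and complication status, and a single-pass 3-SD screen on
BMI, HOMA2-B and HOMA2-IR (means/SDs taken over the completeness-filtered
pool).  Each excluded record is attributed to the first failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .indices import compute_egfr

GADA_THRESHOLD = 5.0

#: Composite complication -> component flags (logical OR).
COMPOSITES: Dict[str, List[str]] = {
    "pdr": ["proliferative_retinopathy", "laser_treatment", "blindness"],
    "ckd": ["egfr_lt_60", "documented_nephropathy", "dialysis", "esrd"],
    "neuropathy": ["peripheral_neuropathy"],
    "cvd": ["mi", "stroke"],
}

#: Fields that must be complete for a record to be analyzable.
REQUIRED_COMPLETE = [
    "bmi", "age_at_onset", "hba1c", "homa2_b", "homa2_ir", "sex", "duration",
]
OUTLIER_FEATURES = ["bmi", "homa2_b", "homa2_ir"]
DURATION_CUTOFF = 3.0  # years; >= 3 -> long_term


def classify_gada(value) -> pd.Series | str:
    """GADA status from concentration (U/ml): >=5 positive, <5 negative, missing unknown."""
    scalar = np.isscalar(value) or value is None
    vals = pd.Series([value] if scalar else value, dtype=float)
    if (vals.dropna() < 0).any():
        raise ValueError("negative GADA concentration")
    out = pd.Series("unknown", index=vals.index, dtype=object)
    out[vals >= GADA_THRESHOLD] = "positive"
    out[vals < GADA_THRESHOLD] = "negative"
    return out.iloc[0] if scalar else out


def derive_complications(df: pd.DataFrame) -> pd.DataFrame:
    """Add eGFR, the ``egfr_lt_60`` component and the four composite flags.

    Missing component flags count as False (absence of a record is absence of
    the diagnosis); per-component missingness is reported via the returned
    frame's ``attrs["component_missingness"]``.  The eGFR component is strictly
    ``eGFR < 60``; eGFR itself requires creatinine and age.
    """
    out = df.copy()
    with np.errstate(invalid="ignore"):
        ok = out["creatinine"].notna() & out["age"].notna()
        egfr = np.full(len(out), np.nan)
        if ok.any():
            egfr[ok.to_numpy()] = compute_egfr(
                out.loc[ok, "creatinine"], out.loc[ok, "age"], out.loc[ok, "sex"]
            )
    out["egfr"] = egfr
    out["egfr_lt_60"] = pd.Series(egfr < 60.0, index=out.index)  # NaN egfr -> False
    missingness = {}
    for comp, parts in COMPOSITES.items():
        acc = pd.Series(False, index=out.index)
        for p in parts:
            if p not in out.columns:
                out[p] = np.nan
            missingness[p] = float(out[p].isna().mean())
            acc |= out[p].notna() & out[p].astype("boolean").fillna(False).astype(bool)
        out[comp] = acc
    out.attrs["component_missingness"] = missingness
    return out


@dataclass
class ExclusionLedger:
    """Per-rule exclusion counts and row ids (first-failing-rule attribution)."""

    rules: Dict[str, List[str]] = field(default_factory=dict)

    def add(self, rule: str, ids: List[str]) -> None:
        if ids:
            self.rules.setdefault(rule, []).extend(ids)

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.rules.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "n_excluded": len(ids), "row_ids": ",".join(ids)}
            for rule, ids in self.rules.items()
        ]
        return pd.DataFrame(rows, columns=["rule", "n_excluded", "row_ids"])


def apply_inclusion_filters(df: pd.DataFrame) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the eligibility rules; return the analysis cohort and the ledger.

    Rule order: (1) age at onset > 18 (strict), (2) completeness of the
    clustering features, sex and duration, (3) single-pass |z| > 3 screen on
    BMI, HOMA2-B, HOMA2-IR with mean/SD from the post-completeness pool.
    """
    ledger = ExclusionLedger()
    work = df.copy()

    young = ~(work["age_at_onset"] > 18.0)
    ledger.add("age_le_18", list(work.loc[young, "patient_id"]))
    work = work[~young]

    incomplete = work[REQUIRED_COMPLETE].isna().any(axis=1)
    ledger.add("incomplete", list(work.loc[incomplete, "patient_id"]))
    work = work[~incomplete]

    # bounds for all three features from the post-completeness pool, applied in one pass
    stats = {f: (work[f].mean(), work[f].std(ddof=1)) for f in OUTLIER_FEATURES}
    remaining = work
    for feat in OUTLIER_FEATURES:
        mean, sd = stats[feat]
        z = (remaining[feat] - mean) / sd
        outlier = remaining.index[np.abs(z) > 3.0]
        ledger.add(f"3sd_{feat}", list(remaining.loc[outlier, "patient_id"]))
        remaining = remaining.drop(index=outlier)
    work = remaining

    if work.empty:
        raise ValueError("no records remain after inclusion filters")
    assert ledger.n_excluded + len(work) == len(df)
    return work.reset_index(drop=True), ledger


def split_duration(df: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (new_onset, long_term) by disease duration.

    Duration < 3 years -> new-onset; >= 3 years -> long-term (the boundary value
    3.0 is assigned to the long-term stratum).  Negative durations are invalid.
    """
    dur = df["duration"].astype(float)
    if (dur.dropna() < 0).any():
        raise ValueError("negative diabetes duration")
    new_onset = df[dur < DURATION_CUTOFF].copy()
    long_term = df[dur >= DURATION_CUTOFF].copy()
    new_onset["stratum"] = "new_onset"
    long_term["stratum"] = "long_term"
    return new_onset, long_term
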