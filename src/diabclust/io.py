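"""Reading and writing cohort tables, genotype data, SNP panels and configs.

All column-name conventions live here.  User files with different headers are
adapted through an explicit *dialect* mapping (canonical name -> file header);
no renaming heuristics are applied.  Canonical units are fixed: HbA1c in %,
fasting glucose in mmol/L, C-peptide in nmol/L, creatinine in umol/L, GADA in
U/ml.  Missing values may be encoded as "" / "NA" / "NaN" on input and are
written back as "NA".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import CohortConfig

MISSING_MARKERS = ["", "NA", "NaN", "nan"]
MISSING_OUT = "NA"

#: Canonical cohort columns, in output order.
NUMERIC_COLUMNS = [
    "age",
    "age_at_onset",
    "duration",
    "bmi",
    "waist",
    "hba1c",
    "fasting_glucose",
    "c_peptide",
    "gada",
    "creatinine",
    "homa2_b",
    "homa2_ir",
]
COMPONENT_COLUMNS = [
    "proliferative_retinopathy",
    "laser_treatment",
    "blindness",
    "documented_nephropathy",
    "dialysis",
    "esrd",
    "mi",
    "stroke",
    "peripheral_neuropathy",
]
BOOL_COLUMNS = COMPONENT_COLUMNS + ["insulin_treatment"]
CANONICAL_COLUMNS = ["patient_id", "sex"] + NUMERIC_COLUMNS + BOOL_COLUMNS

#: Columns that must be resolvable when reading a cohort file.
MANDATORY_COLUMNS = ["patient_id", "sex", "age_at_onset", "duration", "bmi", "hba1c"]


class ConfigurationError(ValueError):
    """A file or config does not satisfy the declared contract."""


class RowParseError(ValueError):
    """A row-level numeric value could not be parsed."""


@dataclass
class CohortTable:
    """Patient-level cohort table in canonical columns/units.

    ``df`` has one row per patient; ``source`` records provenance; the dialect
    maps canonical names to the original file headers.
    """

    df: pd.DataFrame
    source: str = "synthetic"
    column_dialect: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.df["patient_id"].astype(str)
        if (ids == "").any() or ids.isna().any():
            raise ConfigurationError("empty patient IDs")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate patient ID: {dup!r}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GenotypeMatrix:
    """Per-sample additive risk-allele dosages for a SNP panel.

    ``dosages`` is samples x rsids, values in [0, 2] or NaN; ``snps`` carries
    rsid, chrom, pos, risk_allele, other_allele.
    """

    snps: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if self.snps["rsid"].duplicated().any():
            raise ConfigurationError("duplicate rsids in panel")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 2))
        if not ok.all():
            raise ConfigurationError("dosages must lie in [0, 2] or be missing")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.dosages.index)


def _apply_dialect(df: pd.DataFrame, dialect: Optional[Dict[str, str]]) -> pd.DataFrame:
    if dialect:
        rename = {v: k for k, v in dialect.items() if v in df.columns}
        df = df.rename(columns=rename)
    return df


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = []
    for i, v in enumerate(series):
        if pd.isna(v) or str(v).strip() in MISSING_MARKERS:
            out.append(np.nan)
            continue
        key = str(v).strip().lower()
        if key in mapping:
            out.append(mapping[key])
        else:
            raise RowParseError(f"row {i}: unparseable boolean {v!r} in column {name!r}")
    return pd.Series(out, index=series.index, dtype=object)


def read_cohort(path: str | Path, dialect: Optional[Dict[str, str]] = None) -> CohortTable:
    """Read a cohort CSV/TSV into canonical columns.

    Raises :class:`ConfigurationError` naming the first missing mandatory
    column, and :class:`RowParseError` with the row index for unparseable
    numerics.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = _apply_dialect(raw, dialect)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ConfigurationError(f"mandatory column missing: {col!r}")
    df = pd.DataFrame()
    df["patient_id"] = raw["patient_id"].astype(str)
    df["sex"] = raw["sex"].str.strip().str.lower()
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise RowParseError(
            f"row {int(np.argmax(bad_sex.to_numpy()))}: sex must be male/female"
        )
    for col in NUMERIC_COLUMNS:
        if col not in raw.columns:
            df[col] = np.nan
            continue
        vals = raw[col].replace(dict.fromkeys(MISSING_MARKERS, None))
        parsed = pd.to_numeric(vals, errors="coerce")
        bad = parsed.isna() & vals.notna() & (vals.astype(str).str.strip() != "")
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise RowParseError(f"row {i}: unparseable numeric {raw[col].iloc[i]!r} in column {col!r}")
        df[col] = parsed.astype(float)
    for col in BOOL_COLUMNS:
        df[col] = _parse_bool(raw[col], col) if col in raw.columns else np.nan
    return CohortTable(df=df, source=str(path), column_dialect=dialect or {})


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (missing -> "NA")."""
    df = table.df.copy()
    for col in BOOL_COLUMNS:
        df[col] = df[col].map(lambda v: MISSING_OUT if pd.isna(v) else str(bool(v)).lower())
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_OUT, float_format="%.10g")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a SNP panel TSV (rsid, risk_allele, optional gene/chrom/bp/other_allele/raf)."""
    panel = pd.read_csv(path, sep="\t", dtype={"rsid": str, "risk_allele": str})
    for col in ("rsid", "risk_allele"):
        if col not in panel.columns:
            raise ConfigurationError(f"panel is missing column {col!r}")
    if panel["rsid"].duplicated().any():
        raise ConfigurationError("duplicate rsids in panel")
    return panel


def read_genotypes(
    path: str | Path,
    fmt: str,
    panel: pd.DataFrame,
    cohort_ids: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Read genotypes from a VCF or a dosage TSV, oriented to the risk allele.

    ``fmt`` is ``"vcf"`` or ``"dosage_tsv"``.  VCF genotypes are mapped to
    additive ALT counts and flipped when the declared risk allele is REF; a SNP
    whose risk allele is neither REF nor ALT is skipped with a warning.  Dosage
    TSV columns are either ``rsid`` (already risk-oriented) or ``rsid:ALLELE``
    declaring the counted allele.  With ``cohort_ids`` given, a sample-ID
    mismatch is reported as a set difference.
    """
    panel = panel.set_index("rsid", drop=False)
    if fmt == "vcf":
        snps_rows, dos_cols = [], {}
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for rec in vcf:
            rsid = rec.ID
            if rsid is None or rsid not in panel.index:
                continue
            risk = panel.loc[rsid, "risk_allele"]
            ref, alts = rec.REF, rec.ALT
            if not alts:
                continue
            alt = alts[0]
            if risk not in (ref, alt):
                warnings.warn(f"{rsid}: risk allele {risk} not among REF/ALT; skipped")
                continue
            gts = rec.gt_types  # 0=hom_ref 1=het 2=unknown 3=hom_alt
            alt_count = np.select(
                [gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan
            )
            dosage = alt_count if risk == alt else 2.0 - alt_count
            other = ref if risk == alt else alt
            snps_rows.append(
                {"rsid": rsid, "chrom": str(rec.CHROM), "pos": int(rec.POS),
                 "risk_allele": risk, "other_allele": other}
            )
            dos_cols[rsid] = dosage
        dosages = pd.DataFrame(dos_cols, index=pd.Index(samples, name="sample_id"))
        snps = pd.DataFrame(snps_rows, columns=["rsid", "chrom", "pos", "risk_allele", "other_allele"])
    elif fmt == "dosage_tsv":
        raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in raw.columns:
            raise ConfigurationError("dosage TSV must have a sample_id column")
        raw = raw.set_index("sample_id")
        snps_rows, dos_cols = [], {}
        for col in raw.columns:
            rsid, _, counted = col.partition(":")
            if rsid not in panel.index:
                continue
            risk = str(panel.loc[rsid, "risk_allele"])
            other = str(panel.loc[rsid].get("other_allele", ""))
            vals = raw[col].astype(float).to_numpy()
            if counted == "" or counted == risk:
                dosage = vals
            elif other and counted not in (risk, other):
                warnings.warn(f"{rsid}: counted allele {counted} not among declared alleles; skipped")
                continue
            else:
                dosage = 2.0 - vals
            snps_rows.append(
                {"rsid": rsid,
                 "chrom": str(panel.loc[rsid].get("chrom", "")),
                 "pos": int(panel.loc[rsid].get("bp", 0) or 0),
                 "risk_allele": risk, "other_allele": other}
            )
            dos_cols[rsid] = dosage
        dosages = pd.DataFrame(dos_cols, index=raw.index.rename("sample_id"))
        snps = pd.DataFrame(snps_rows, columns=["rsid", "chrom", "pos", "risk_allele", "other_allele"])
    else:
        raise ConfigurationError(f"unknown genotype format {fmt!r}")

    if cohort_ids is not None:
        got, want = set(dosages.index), set(map(str, cohort_ids))
        if got != want:
            warnings.warn(
                "sample-ID mismatch with cohort: "
                f"{len(want - got)} cohort-only, {len(got - want)} genotype-only"
            )
    return GenotypeMatrix(snps=snps, dosages=dosages)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a risk-oriented dosage TSV (columns ``rsid:RISK_ALLELE``)."""
    out = gm.dosages.copy()
    risk = gm.snps.set_index("rsid")["risk_allele"]
    out.columns = [f"{c}:{risk[c]}" for c in out.columns]
    out.to_csv(path, sep="\t", na_rep=MISSING_OUT, float_format="%.10g")


def load_config(path: str | Path) -> CohortConfig:
    """Load a cohort config from JSON or YAML and validate it."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() in {".yml", ".yaml"} else json.loads(text)
    return CohortConfig.model_validate(data)


def save_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))
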