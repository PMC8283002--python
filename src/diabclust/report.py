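"""End-to-end orchestration: simulate -> indices -> phenotype -> cluster ->
risks -> genetics, with a run manifest and table-layout outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import run_clustering_pipeline
from .config import CohortConfig
from .genetics import run_genetics
from .io import CohortTable, write_cohort, write_genotypes
from .phenotyping import apply_inclusion_filters, derive_complications, split_duration
from .risk import run_risk_models
from .simulate import generate_cohort

log = logging.getLogger("diabclust")

SUMMARY_CONTINUOUS = [
    "age", "age_at_onset", "duration", "hba1c", "bmi", "waist",
    "homa2_b", "homa2_ir", "c_peptide",
]
SUMMARY_BINARY = ["pdr", "ckd", "neuropathy", "cvd", "insulin_treatment"]


def summarize_cohort(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Descriptive table: mean (SD) for continuous fields, % for binary."""
    rows = [{"phenotype": "n", "value": f"{len(df)}"}]
    men = float((df["sex"] == "male").mean()) * 100
    rows.append({"phenotype": "men_pct", "value": f"{men:.1f}"})
    for col in SUMMARY_CONTINUOUS:
        if col in df.columns:
            rows.append({
                "phenotype": col,
                "value": f"{df[col].mean():.1f} ({df[col].std(ddof=1):.1f})",
            })
    for col in SUMMARY_BINARY:
        if col in df.columns:
            pct = float(df[col].fillna(False).astype(bool).mean()) * 100
            rows.append({"phenotype": f"{col}_pct", "value": f"{pct:.1f}"})
    out = pd.DataFrame(rows)
    out.attrs["stratum"] = stratum
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: CohortConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
    runs: int = 100,
    with_genotypes: bool = True,
) -> Dict:
    """Run the full pipeline on a synthetic cohort; write tables and a manifest.

    Returns the manifest dict.  Outputs: cohort/truth TSVs, per-stratum
    descriptive summaries, cluster-frequency table, per-cluster centroid
    tables, complication OR tables, SNP association table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "stages": {},
        "warnings": [],
        "files": {},
    }

    log.info("[simulate] generating cohort (seed=%d)", config.seed)
    syn = generate_cohort(config, with_genotypes=with_genotypes)
    write_cohort(syn.cohort, out / "cohort.tsv")
    syn.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {"n": len(syn.cohort)}

    log.info("[phenotype] deriving complications and applying filters")
    df = derive_complications(syn.cohort.df)
    df, ledger = apply_inclusion_filters(df)
    ledger.to_frame().to_csv(out / "exclusions.tsv", sep="\t", index=False)
    new_onset, long_term = split_duration(df)
    manifest["stages"]["phenotype"] = {
        "n_included": len(df), "n_excluded": ledger.n_excluded,
        "n_new_onset": len(new_onset), "n_long_term": len(long_term),
    }

    freq_rows = []
    assignments = {}
    for stratum, part in (("new_onset", new_onset), ("long_term", long_term)):
        if len(part) == 0:
            continue
        log.info("[cluster] %s stratum (n=%d)", stratum, len(part))
        res = run_clustering_pipeline(
            part, stratum, runs=runs, seed=config.seed,
        )
        assignments[stratum] = res
        merged = part.reset_index(drop=True).join(
            res.assignments[["cluster_label", "provenance", "silhouette"]]
        )
        assignments[f"{stratum}_df"] = merged
        res.assignments.to_csv(out / f"assignments_{stratum}.tsv", sep="\t", index=False)
        if len(res.centroids):
            res.centroids.to_csv(out / f"centroids_{stratum}.tsv", sep="\t")
        summarize_cohort(part, stratum).to_csv(
            out / f"summary_{stratum}.tsv", sep="\t", index=False
        )
        counts = res.assignments["cluster_label"].value_counts()
        for label, n in counts.items():
            freq_rows.append({
                "stratum": stratum, "cluster_label": label, "n": int(n),
                "pct": 100.0 * n / len(part),
            })
        manifest["stages"][f"cluster_{stratum}"] = {
            "n": len(part), "asw": getattr(res, "solutions", None)
            and {s: sol.asw for s, sol in res.solutions.items()},
        }
    pd.DataFrame(freq_rows).to_csv(out / "cluster_frequencies.tsv", sep="\t", index=False)

    for stratum in ("new_onset", "long_term"):
        key = f"{stratum}_df"
        if key not in assignments:
            continue
        merged = assignments[key]
        merged = merged[merged["cluster_label"].isin(
            ["SAID", "SIDD", "SIRD", "MOD", "MARD", "IROD1", "IROD2"]
        )]
        log.info("[risks] %s stratum", stratum)
        table = run_risk_models(merged, stratum)
        table.to_csv(out / f"risks_{stratum}.tsv", sep="\t", index=False)
        manifest["stages"][f"risks_{stratum}"] = {"n_tests": len(table)}

    if with_genotypes and syn.genotypes is not None and "long_term_df" in assignments:
        log.info("[genetics] IROD2 contrasts")
        write_genotypes(syn.genotypes, out / "genotypes.tsv")
        lt = assignments["long_term_df"]
        snp_table = run_genetics(lt, syn.genotypes)
        snp_table.to_csv(out / "snp_associations.tsv", sep="\t", index=False)
        manifest["stages"]["genetics"] = {"n_snps": syn.genotypes.dosages.shape[1]}

    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
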