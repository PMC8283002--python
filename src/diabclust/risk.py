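"""Cluster-wise complication risks: adjusted logistic odds ratios with FDR.

For each complication, a maximum-likelihood logistic regression of the outcome
on cluster membership (indicator-coded, MARD as reference) adjusted for age,
sex (male=1) and diabetes duration.  Odds ratios with 95% Wald confidence
intervals; Benjamini-Hochberg FDR across all cluster x complication tests
within a duration stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import COMPLICATIONS

Z975 = 1.959963984540054


@dataclass
class AssociationResult:
    """One (cluster, outcome) odds-ratio estimate versus the reference."""

    outcome: str
    predictor: str
    or_hat: float
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    n: int = 0
    n_events: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "cluster": self.predictor,
            "or": self.or_hat, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "q": self.q, "n": self.n, "n_events": self.n_events,
            "converged": self.converged,
        }


def fit_complication_model(
    df: pd.DataFrame,
    outcome: str,
    reference: str = "MARD",
    covariates: Sequence[str] = ("age", "sex", "duration"),
    cluster_col: str = "cluster_label",
) -> List[AssociationResult]:
    """Fit the MARD-reference logistic model for one complication.

    ``df`` carries the boolean outcome column, cluster labels, and the
    covariates (sex as "male"/"female").  Returns one result per non-reference
    cluster; non-convergence or separation is flagged, never silently dropped.
    """
    y = df[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} is constant")
    clusters = df[cluster_col].astype(str)
    if reference not in set(clusters):
        raise ValueError(f"reference cluster {reference!r} absent")
    others = [c for c in pd.unique(clusters) if c != reference]
    others.sort()
    Xcols = {}
    for c in others:
        Xcols[f"cluster[{c}]"] = (clusters == c).astype(float).to_numpy()
    for cov in covariates:
        if cov == "sex":
            Xcols["sex"] = (df["sex"] == "male").astype(float).to_numpy()
        else:
            Xcols[cov] = df[cov].astype(float).to_numpy()
    X = sm.add_constant(pd.DataFrame(Xcols), has_constant="add")
    converged = True
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit, converged = None, False
    results = []
    for c in others:
        name = f"cluster[{c}]"
        n_c = int((clusters == c).sum() + (clusters == reference).sum())
        ev = int(y[(clusters == c) | (clusters == reference)].sum())
        if fit is None or not converged or not np.isfinite(fit.bse[name]):
            results.append(AssociationResult(
                outcome=outcome, predictor=c, or_hat=np.nan, ci_low=np.nan,
                ci_high=np.nan, p=np.nan, n=n_c, n_events=ev, converged=False,
            ))
            continue
        beta, se = fit.params[name], fit.bse[name]
        results.append(AssociationResult(
            outcome=outcome, predictor=c,
            or_hat=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z975 * se)),
            ci_high=float(np.exp(beta + Z975 * se)),
            p=float(fit.pvalues[name]),
            n=n_c, n_events=ev, converged=True,
        ))
    return results


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_risk_models(
    df: pd.DataFrame,
    stratum: str,
    reference: str = "MARD",
    outcomes: Sequence[str] = COMPLICATIONS,
    min_events: int = 5,
) -> pd.DataFrame:
    """All complications for one stratum, with FDR over the stratum's tests.

    In the new-onset stratum an outcome with fewer than ``min_events`` events
    is skipped (mirroring sparse proliferative-retinopathy counts), recorded
    with a ``skipped`` row.
    """
    rows: List[AssociationResult] = []
    skipped = []
    for outcome in outcomes:
        n_events = int(df[outcome].astype(bool).sum())
        if stratum == "new_onset" and n_events < min_events:
            skipped.append(outcome)
            continue
        rows.extend(fit_complication_model(df, outcome, reference=reference))
    ok = [r for r in rows if r.converged]
    if ok:
        qs = adjust_fdr([r.p for r in ok])
        for r, q in zip(ok, qs):
            r.q = float(q)
    table = pd.DataFrame([r.to_dict() for r in rows])
    table.attrs["skipped_outcomes"] = skipped
    table.attrs["stratum"] = stratum
    return table
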