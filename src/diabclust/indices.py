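"""Clinical indices: HOMA2 beta-cell/insulin-resistance surrogates and MDRD eGFR.

The homeostasis-model-assessment-2 (HOMA2) indices are defined by an external
closed-source calculator (an iterative structural model).  That model is not
reimplemented here; instead a transparent surrogate maps C-peptide (nmol/L) and
fasting glucose (mmol/L) to the same scales:

    I  = k * CP            (insulin-equivalent; calibration k, default 7.5)
    B  = 20 * I / (G - 3.5)   [% beta-cell function]
    IR = I * G / 22.5         [insulin-resistance index]

mirroring the classical HOMA1 forms.  A ``passthrough`` backend copies
pre-computed HOMA2 columns unchanged, and the synthetic generator emits indices
directly, so nothing downstream depends on the surrogate's calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Documented domain of the external HOMA2 calculator (glucose, mmol/L).
GLUCOSE_DOMAIN = (3.5, 25.0)
DEFAULT_K = 7.5


@dataclass
class HomaResult:
    """HOMA2 indices plus per-row flags for out-of-domain glucose."""

    homa2_b: pd.Series
    homa2_ir: pd.Series
    flagged: pd.Series  # True where glucose was clamped or the index is undefined
    backend: str


def compute_homa(
    df: pd.DataFrame,
    backend: str = "surrogate",
    k: float = DEFAULT_K,
) -> HomaResult:
    """Compute HOMA2-B (%) and HOMA2-IR from a cohort frame.

    ``surrogate`` uses ``c_peptide`` and ``fasting_glucose``; glucose above the
    calculator domain is clamped to 25 (flagged), glucose at or below 3.5 makes
    both indices undefined for that row (flagged missing, not an exception).
    ``passthrough`` returns the existing ``homa2_b``/``homa2_ir`` columns.
    """
    if backend == "passthrough":
        return HomaResult(
            homa2_b=df["homa2_b"].astype(float),
            homa2_ir=df["homa2_ir"].astype(float),
            flagged=pd.Series(False, index=df.index),
            backend=backend,
        )
    if backend != "surrogate":
        raise ValueError(f"unknown HOMA backend {backend!r}")
    cp = df["c_peptide"].astype(float)
    g = df["fasting_glucose"].astype(float)
    if (cp.dropna() < 0).any() or (g.dropna() < 0).any():
        raise ValueError("negative C-peptide or glucose")
    clamped_high = g > GLUCOSE_DOMAIN[1]
    g_eff = g.clip(upper=GLUCOSE_DOMAIN[1])
    undefined = g_eff <= GLUCOSE_DOMAIN[0]
    insulin = k * cp
    with np.errstate(divide="ignore", invalid="ignore"):
        b = 20.0 * insulin / (g_eff - GLUCOSE_DOMAIN[0])
        ir = insulin * g_eff / 22.5
    b = b.where(~undefined)
    ir = ir.where(~undefined)
    return HomaResult(
        homa2_b=b, homa2_ir=ir,
        flagged=(clamped_high | undefined).fillna(False),
        backend=backend,
    )


def compute_egfr(creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) by the 4-variable MDRD equation.

    ``186 * (creatinine/88.4)^-1.154 * age^-0.203``, multiplied by 0.742 for
    female sex.  Creatinine in umol/L, age in years; ``sex`` is "male"/"female"
    (scalar or array).  Inputs must be strictly positive.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(creatinine[~np.isnan(creatinine)] <= 0) or np.any(age[~np.isnan(age)] <= 0):
        raise ValueError("creatinine and age must be positive")
    sex_arr = np.asarray(sex)
    female = sex_arr == "female"
    if not np.all((sex_arr == "male") | female):
        raise ValueError("sex must be 'male' or 'female'")
    egfr = 186.0 * (creatinine / 88.4) ** -1.154 * age**-0.203
    egfr = np.where(female, egfr * 0.742, egfr)
    return egfr if egfr.ndim else float(egfr)
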