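"""Lean-meat-percentage phenotype: ultrasound formula and covariate adjustment.

LMP (percent of carcass lean meat) is predicted from two ultrasound
measurements taken at ~120 kg body weight — backfat thickness (mm) and
longissimus-muscle transection area (cm^2) — by the linear carcass-grading
model

    LMP = 0.54 * (80.95 - 16.44 * backfat + 4.693 * loin_area)

Association scans use not LMP itself but its residual (``adj_p``) after
removing additive fixed effects of sex and sampling batch by ordinary least
squares.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["compute_lmp", "adjust_phenotype", "LMP_INTERCEPT", "LMP_BF_COEF", "LMP_LMA_COEF", "LMP_SCALE"]

LMP_INTERCEPT = 80.95
LMP_BF_COEF = -16.44   # per mm backfat
LMP_LMA_COEF = 4.693   # per cm^2 loin-muscle area
LMP_SCALE = 0.54


def compute_lmp(backfat, loin_area):
    """Lean meat percentage from backfat (mm) and loin-muscle area (cm^2).

    Affine in both inputs; no clamping is applied, so implausible
    measurements yield implausible percentages rather than silent truncation.
    """
    bf = np.asarray(backfat, dtype=float)
    lma = np.asarray(loin_area, dtype=float)
    if (bf < 0).any() or (lma < 0).any():
        raise ValueError("backfat and loin_area must be non-negative")
    out = LMP_SCALE * (LMP_INTERCEPT + LMP_BF_COEF * bf + LMP_LMA_COEF * lma)
    return float(out) if out.ndim == 0 else out


def adjust_phenotype(metadata: pd.DataFrame) -> pd.DataFrame:
    """Residualize LMP on sex and batch; returns a copy with ``adj_p`` filled.

    ``metadata`` must have columns ``sex`` and ``batch`` plus either ``lmp``
    or both ``backfat_mm`` and ``lma_cm2`` (from which LMP is computed).
    The model is additive fixed effects with intercept, fitted by least
    squares on indicator columns; a factor with a single level is dropped
    and collinear indicator columns are handled by the pseudoinverse (the
    fitted values, hence the residuals, are unaffected by the coefficient
    ambiguity).
    """
    md = metadata.copy()
    if "lmp" not in md.columns:
        if not {"backfat_mm", "lma_cm2"} <= set(md.columns):
            raise ValueError("need 'lmp' or both 'backfat_mm' and 'lma_cm2'")
        md["lmp"] = compute_lmp(md["backfat_mm"].to_numpy(), md["lma_cm2"].to_numpy())
    for col in ("sex", "batch"):
        if col not in md.columns:
            raise ValueError(f"metadata missing {col!r} column")
        if md[col].isna().any():
            raise ValueError(f"missing values in {col!r}")

    y = md["lmp"].to_numpy(dtype=float)
    n = len(md)
    cols = [np.ones(n)]
    for col in ("sex", "batch"):
        levels = sorted(md[col].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"factor {col!r} has a single level; omitted")
            continue
        for lev in levels[1:]:  # reference coding, first level baseline
            cols.append((md[col].astype(str) == lev).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if n <= X.shape[1]:
        raise ValueError("more coefficients than samples")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    md["adj_p"] = y - X @ beta
    return md
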