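"""Prepare analysis-ready polygenic-score predictors.

Raw PGSs are regressed on genotyping-platform dummies and the first 10
genetic PCs per trait x role, the residuals are standardized to zero mean and
unit variance over the observed values, and missing parental scores are then
mean-imputed with zero (the mean of a standardized score). Standardizing
before imputation keeps the observed-score scale intact; the imputed zeros
carry no information and simply retain the family in the analysis.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_PC_COLS = tuple(f"PC{i}" for i in range(1, 11))
DEFAULT_PLATFORM_COLS = ("platform_2", "platform_3")

_REQUIRED_COLS = ("individual_id", "role", "trait", "value", "missing")


def _validate(pgs: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in pgs.columns]
    if missing:
        raise KeyError(f"PGS table missing columns {missing}")


def residualize_standardize(
    pgs: pd.DataFrame,
    covariates: pd.DataFrame,
    pc_cols=DEFAULT_PC_COLS,
    platform_cols=DEFAULT_PLATFORM_COLS,
) -> pd.DataFrame:
    """OLS-residualize each trait x role PGS on platform dummies + PCs, then
    z-score (observed entries only; missing entries stay missing)."""
    _validate(pgs)
    cols = list(platform_cols) + list(pc_cols)
    absent = [c for c in cols if c not in covariates.columns]
    if absent:
        raise KeyError(f"covariates missing columns {absent}")

    out = pgs.copy()
    for (_, _), idx in out.groupby(["trait", "role"]).groups.items():
        block = out.loc[idx]
        obs = block.index[~block["missing"].astype(bool)]
        if len(obs) == 0:
            continue
        ids = block.loc[obs, "individual_id"]
        X = np.column_stack(
            [np.ones(len(obs))] + [covariates.loc[ids, c].to_numpy(dtype=float) for c in cols]
        )
        y = block.loc[obs, "value"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            raise ValueError(
                f"zero residual variance for trait={block['trait'].iloc[0]!r} "
                f"role={block['role'].iloc[0]!r}"
            )
        out.loc[obs, "value"] = (resid - resid.mean()) / sd
    return out


def mean_impute_parent(pgs: pd.DataFrame) -> pd.DataFrame:
    """Set missing maternal/paternal entries to 0 and flag them imputed.

    Zero is the mean of a standardized score, so this is mean imputation on
    the analysis scale. Missing offspring scores are a design violation and
    raise an error.
    """
    _validate(pgs)
    out = pgs.copy()
    miss = out["missing"].astype(bool)
    bad_off = out.loc[miss & (out["role"] == "offspring"), "individual_id"].unique()
    if len(bad_off):
        raise ValueError(
            f"offspring PGSs may not be missing: {sorted(bad_off)[:5]}"
        )
    parent_miss = miss & out["role"].isin(["mother", "father"])
    out["imputed"] = False
    out.loc[parent_miss, "value"] = 0.0
    out.loc[parent_miss, "imputed"] = True
    return out


def pgs_wide(pgs: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long PGS table to individual_id x trait."""
    return pgs.pivot_table(index="individual_id", columns="trait", values="value")
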