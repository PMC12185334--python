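"""Methylation preprocessing: QC filtering, outlier masking, imputation,
covariate residualization, and top-variance probe selection.

The matrix moves through explicit states raw -> masked -> imputed ->
residualized; each operation checks its input state so stages cannot be run
out of order. Beta-values live in [0, 1]; residuals are unbounded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

STATES = ("raw", "masked", "imputed", "residualized")

#: covariates regressed out of beta-values before association testing
DEFAULT_RESIDUALIZE_COVARIATES = (
    "sex",
    "age",
    "prop_epithelial",
    "prop_nk",
    "array_row",
    "plate",
)


@dataclass
class MethylMatrix:
    """Samples x probes methylation matrix with an explicit processing state.

    Missing entries are NaN. In beta states ("raw", "masked") all non-missing
    values must lie in [0, 1].
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in ("raw", "masked"):
            v = self.values.to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta-values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def _require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise ValueError(
                f"operation requires state in {allowed}, matrix is {self.state!r}"
            )


def read_methyl_tsv(path, state: str = "raw") -> MethylMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "sample_id"
    return MethylMatrix(values=values, state=state)


def write_methyl_tsv(mm: MethylMatrix, path) -> None:
    mm.values.to_csv(path, sep="\t")


def qc_filter(
    mm: MethylMatrix, manifest: pd.DataFrame, min_success: float = 0.95
) -> MethylMatrix:
    """Drop probes flagged cross-reactive / SNP-overlapping / sex-chromosome,
    or with success rate strictly below ``min_success``; samples unchanged."""
    mm._require_state("raw")
    man = manifest.set_index("probe_id")
    unknown = mm.values.columns.difference(man.index)
    if len(unknown):
        raise KeyError(
            f"{len(unknown)} matrix probes absent from manifest, e.g. {list(unknown[:3])}"
        )
    man = man.loc[mm.values.columns]
    bad = (
        man["cross_reactive"].astype(bool)
        | man["snp_overlap"].astype(bool)
        | man["sex_chromosome"].astype(bool)
        | (man["success_rate"] < min_success)
    )
    keep = mm.values.columns[~bad.to_numpy()]
    logger.info("qc_filter: %d probes in, %d retained, %d dropped",
                mm.n_probes, len(keep), mm.n_probes - len(keep))
    return MethylMatrix(values=mm.values[keep], state="raw")


def mask_outliers_iqr(
    mm: MethylMatrix, k: float = 3.0
) -> tuple[MethylMatrix, int]:
    """Mask per-probe values outside [Q1 - k*IQR, Q3 + k*IQR] (single pass).

    Quantiles use linear interpolation between order statistics and are
    computed once on the original non-missing values. Probes with fewer than
    4 non-missing values are left unmasked with a logged warning.
    """
    mm._require_state("raw")
    v = mm.values.to_numpy(dtype=float).copy()
    n_ok = np.sum(np.isfinite(v), axis=0)
    thin = n_ok < 4
    if thin.any():
        logger.warning(
            "mask_outliers_iqr: %d probes with < 4 non-missing values left unmasked",
            int(thin.sum()),
        )
    with np.errstate(invalid="ignore"):
        q1 = np.nanquantile(v, 0.25, axis=0, method="linear")
        q3 = np.nanquantile(v, 0.75, axis=0, method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = np.isfinite(v) & ((v < lo) | (v > hi)) & ~thin
    n_masked = int(out.sum())
    v[out] = np.nan
    masked = pd.DataFrame(v, index=mm.values.index, columns=mm.values.columns)
    logger.info("mask_outliers_iqr: masked %d values (k=%g)", n_masked, k)
    return MethylMatrix(values=masked, state="masked"), n_masked


def impute_missing(
    mm: MethylMatrix,
    max_missing: float = 0.05,
    method: str = "mean",
    n_components: int = 5,
    n_iter: int = 20,
) -> MethylMatrix:
    """Drop probes with missing fraction strictly above ``max_missing``; fill
    the rest.

    ``method="mean"`` fills each probe's missing entries with its observed
    mean. ``method="svd"`` refines the mean fill by iterating a rank-
    ``n_components`` truncated-SVD reconstruction of the centered matrix
    (an EM-style low-rank imputation).
    """
    mm._require_state("masked", "raw")
    v = mm.values.to_numpy(dtype=float)
    miss_frac = np.mean(~np.isfinite(v), axis=0)
    keep = miss_frac <= max_missing
    if not keep.any():
        raise ValueError("all probes exceed the missingness threshold")
    v = v[:, keep].copy()
    cols = mm.values.columns[keep]
    miss = ~np.isfinite(v)

    col_mean = np.nanmean(np.where(miss, np.nan, v), axis=0)
    v[miss] = np.take(col_mean, np.nonzero(miss)[1])

    if method == "svd" and miss.any():
        r = min(n_components, min(v.shape) - 1)
        for _ in range(n_iter):
            mu = v.mean(axis=0)
            c = v - mu
            u, s, vt = np.linalg.svd(c, full_matrices=False)
            recon = (u[:, :r] * s[:r]) @ vt[:r] + mu
            new = np.clip(recon[miss], 0.0, 1.0)
            if np.max(np.abs(new - v[miss])) < 1e-8:
                v[miss] = new
                break
            v[miss] = new
    elif method != "mean" and method != "svd":
        raise ValueError(f"unknown imputation method {method!r}")

    out = pd.DataFrame(v, index=mm.values.index, columns=cols)
    logger.info(
        "impute_missing: %d probes in, %d retained (max_missing=%g, method=%s)",
        mm.n_probes, len(cols), max_missing, method,
    )
    return MethylMatrix(values=out, state="imputed")


def _expand_design(
    covariates: pd.DataFrame, columns, samples
) -> pd.DataFrame:
    """Intercept + numeric columns + dummy-expanded categoricals (reference
    level dropped), aligned to ``samples``."""
    missing_cols = [c for c in columns if c not in covariates.columns]
    if missing_cols:
        raise KeyError(f"covariates missing columns {missing_cols}")
    sub = covariates.loc[samples, list(columns)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values in {bad}")
    parts = [pd.Series(1.0, index=sub.index, name="intercept")]
    for c in columns:
        col = sub[c]
        if col.dtype.kind in "ifub":
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the dependent columns via pivoted QR
        _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        dependent = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        dependent += [X.columns[p] for p in piv[len(diag):]]
        raise np.linalg.LinAlgError(
            f"covariate design is rank deficient; collinear columns: {dependent}"
        )


def residualize(
    mm: MethylMatrix,
    covariates: pd.DataFrame,
    formula=DEFAULT_RESIDUALIZE_COVARIATES,
) -> MethylMatrix:
    """Replace each probe by its OLS residuals on the covariate design.

    Residuals are orthogonal to every design column; applying the operation
    twice with the same design is a no-op (projection).
    """
    mm._require_state("imputed", "residualized")
    X = _expand_design(covariates, formula, mm.values.index)
    _check_full_rank(X)
    Xa = X.to_numpy(dtype=float)
    Y = mm.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
    resid = Y - Xa @ beta
    out = pd.DataFrame(resid, index=mm.values.index, columns=mm.values.columns)
    return MethylMatrix(values=out, state="residualized")


def select_top_variance(mm: MethylMatrix, q: float = 0.10) -> MethylMatrix:
    """Keep the floor(q * M) probes with the largest sample variance.

    Ties are broken lexicographically on probe id; the retained probes keep
    their original column order.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    m = mm.n_probes
    n_keep = int(np.floor(q * m))
    if n_keep == 0:
        raise ValueError(f"floor(q*M) = 0 for q={q}, M={m}")
    var = mm.values.to_numpy(dtype=float).var(axis=0, ddof=1)
    ids = mm.values.columns.to_numpy(dtype=object)
    order = np.lexsort((ids, -var))  # primary: variance desc, tie-break: id asc
    chosen = np.zeros(m, dtype=bool)
    chosen[order[:n_keep]] = True
    keep = mm.values.columns[chosen]
    logger.info("select_top_variance: retained %d of %d probes (q=%g)", n_keep, m, q)
    return MethylMatrix(values=mm.values[keep], state=mm.state)
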