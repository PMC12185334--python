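"""Per-probe GEE regression of methylation on trio polygenic scores.

For each CpG the residualized beta-value of offspring j in family i is
modelled as

    Y_ij = mu + sum_t (delta_t PGS^t_ij + alpha_m,t PGS^t_m(i)
                       + alpha_p,t PGS^t_p(i)) + b1 D2_ij + b2 D3_ij + e_ij

with six traits (18 PGS predictors), two dataset dummies and an intercept
(21 columns). Families contribute multiple offspring (twins), so standard
errors come from the cluster-robust sandwich estimator with families as
independent clusters:

    cov(beta_hat) = B^{-1} (sum_i U_i U_i') B^{-1},
    B = sum_i X_i' V_i^{-1} X_i,   U_i = X_i' V_i^{-1} r_i,

where V_i is the working covariance. Under the independence working
structure the point estimates coincide with OLS; an exchangeable structure
(moment-estimated within-family correlation, iterated to convergence) is
also provided. Estimation is written directly on the estimating equations;
no model-fitting library is involved.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .famsim import TRAITS
from .methprep import MethylMatrix

logger = logging.getLogger(__name__)

#: result-table role labels for the three PGS predictors per trait
ROLE_TERMS = ("offspring", "maternal", "paternal")


def pgs_term_names(traits=TRAITS) -> list[str]:
    return [f"{t}_{r}" for t in traits for r in ROLE_TERMS]


@dataclass
class DesignMatrix:
    """Offspring x predictor design with family cluster labels.

    Columns: intercept, 18 PGS predictors (trait-major, roles
    offspring -> maternal -> paternal), dataset dummies (dataset 1 reference).
    """

    X: pd.DataFrame
    clusters: np.ndarray
    pgs_terms: list[str]

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.X):
            raise ValueError("cluster labels must cover all design rows")
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing entries")


def build_design(
    pgs: pd.DataFrame,
    pedigree: pd.DataFrame,
    covariates: pd.DataFrame,
    traits=TRAITS,
) -> DesignMatrix:
    """Assemble the trio-PGS design for all offspring in the pedigree.

    Requires a post-imputation PGS table (no missing parental values) and a
    dataset label per offspring; raises listing the offending ids otherwise.
    """
    off = pedigree[pedigree["role"] == "offspring"].copy()
    if off.empty:
        raise ValueError("pedigree contains no offspring")
    parent_ids = pedigree[pedigree["role"] != "offspring"].set_index(
        ["family_id", "role"]
    )["individual_id"]
    mother_of = parent_ids.xs("mother", level="role")
    father_of = parent_ids.xs("father", level="role")

    wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")
    missing_traits = [t for t in traits if t not in wide.columns]
    if missing_traits:
        raise KeyError(f"PGS table lacks traits {missing_traits}")

    off_ids = off["individual_id"].to_numpy()
    mo_ids = mother_of.loc[off["family_id"]].to_numpy()
    fa_ids = father_of.loc[off["family_id"]].to_numpy()
    for ids, who in ((off_ids, "offspring"), (mo_ids, "mother"), (fa_ids, "father")):
        absent = [i for i in ids if i not in wide.index]
        if absent:
            raise KeyError(f"no PGS values for {who} ids {sorted(set(absent))[:5]}")
    block = wide.loc[:, list(traits)]
    if (
        block.loc[off_ids].isna().any().any()
        or block.loc[mo_ids].isna().any().any()
        or block.loc[fa_ids].isna().any().any()
    ):
        raise ValueError(
            "PGS table has missing values; run pgsprep.mean_impute_parent first"
        )

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(off_ids))}
    for t in traits:
        cols[f"{t}_offspring"] = block.loc[off_ids, t].to_numpy()
        cols[f"{t}_maternal"] = block.loc[mo_ids, t].to_numpy()
        cols[f"{t}_paternal"] = block.loc[fa_ids, t].to_numpy()

    ds = covariates.loc[off_ids, "dataset"].to_numpy()
    if pd.isna(ds).any():
        bad = off_ids[pd.isna(ds)]
        raise ValueError(f"offspring lacking a dataset label: {list(bad[:5])}")
    cols["dataset_2"] = (ds == 2).astype(float)
    cols["dataset_3"] = (ds == 3).astype(float)

    X = pd.DataFrame(cols, index=off_ids)
    X.index.name = "sample_id"
    return DesignMatrix(
        X=X,
        clusters=off["family_id"].to_numpy(),
        pgs_terms=pgs_term_names(traits),
    )


@dataclass
class GeeResult:
    """Per-probe GEE fit: coefficients, robust SEs, Wald z and p-values."""

    probe_id: str
    terms: list[str]
    coef: np.ndarray | None
    robust_se: np.ndarray | None
    z: np.ndarray | None
    p: np.ndarray | None
    converged: bool
    n_clusters: int
    working: str
    message: str = ""

    def to_series(self) -> pd.Series:
        data: dict[str, float] = {}
        for k, term in enumerate(self.terms):
            for stat, arr in (
                ("beta", self.coef), ("se", self.robust_se),
                ("z", self.z), ("p", self.p),
            ):
                data[f"{term}__{stat}"] = np.nan if arr is None else arr[k]
        s = pd.Series(data, name=self.probe_id)
        s["converged"] = self.converged
        return s


def _cluster_slices(clusters: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Row-index arrays per cluster, in first-appearance order."""
    labels, inv = np.unique(clusters, return_inverse=True)
    groups = [np.flatnonzero(inv == g) for g in range(len(labels))]
    return labels, groups


def _sandwich(Xa, resid, groups, vinv_blocks=None, bias_reduced=False):
    """Cluster sandwich covariance. ``vinv_blocks`` defaults to identity
    working covariance (independence).

    With ``bias_reduced`` the cluster residuals are inflated by
    (I - H_i)^{-1}, H_i being the cluster leverage (Mancl & DeRouen): the
    plain sandwich underestimates the variance when the number of clusters
    is only moderate, and this correction restores near-nominal coverage.
    """
    k = Xa.shape[1]
    bread = np.zeros((k, k))
    for g, idx in enumerate(groups):
        Xg = Xa[idx]
        XtV = Xg.T if vinv_blocks is None else Xg.T @ vinv_blocks[g]
        bread += XtV @ Xg
    binv = np.linalg.inv(bread)
    meat = np.zeros((k, k))
    for g, idx in enumerate(groups):
        Xg = Xa[idx]
        rg = resid[idx]
        XtV = Xg.T if vinv_blocks is None else Xg.T @ vinv_blocks[g]
        if bias_reduced:
            h = Xg @ binv @ XtV
            rg = np.linalg.solve(np.eye(len(idx)) - h, rg)
        u = XtV @ rg
        meat += np.outer(u, u)
    return binv @ meat @ binv


def _exchangeable_vinv(n_g: int, alpha: float, sigma2: float) -> np.ndarray:
    """Closed-form inverse of sigma2 * [(1-alpha) I + alpha J] (size n_g)."""
    a = 1.0 / (sigma2 * (1.0 - alpha))
    b = -alpha / (sigma2 * (1.0 - alpha) * (1.0 - alpha + alpha * n_g))
    return a * np.eye(n_g) + b * np.ones((n_g, n_g))


def fit_gee_probe(
    y: np.ndarray,
    design: DesignMatrix,
    probe_id: str = "",
    working: str = "independence",
    cov_type: str = "robust",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> GeeResult:
    """Fit the Gaussian identity-link GEE for one probe.

    Independence working structure solves the normal equations directly
    (point estimates identical to OLS); exchangeable iterates between GLS
    updates of beta and a moment estimate of the common within-family
    correlation. Either way the variance is the cluster-robust sandwich and
    p-values use the standard-normal reference for the robust z.
    """
    if working not in ("independence", "exchangeable"):
        raise ValueError(f"unknown working structure {working!r}")
    if cov_type not in ("robust", "bias_reduced"):
        raise ValueError(f"unknown cov_type {cov_type!r}")
    Xa = design.X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != Xa.shape[0]:
        raise ValueError("y is not aligned with the design matrix")
    labels, groups = _cluster_slices(design.clusters)
    if len(labels) < 2:
        raise ValueError("GEE requires at least 2 clusters")
    terms = list(design.X.columns)
    n, k = Xa.shape

    def failure(msg: str) -> GeeResult:
        return GeeResult(probe_id, terms, None, None, None, None,
                         False, len(labels), working, msg)

    if not np.all(np.isfinite(y)):
        return failure("non-finite response values")
    if np.linalg.matrix_rank(Xa) < k:
        return failure("rank-deficient design")

    XtX = Xa.T @ Xa
    beta = np.linalg.solve(XtX, Xa.T @ y)

    vinv_blocks = None
    if working == "exchangeable":
        alpha = 0.0
        for _ in range(max_iter):
            resid = y - Xa @ beta
            sigma2 = resid @ resid / (n - k)
            num = 0.0
            denom_pairs = 0
            for idx in groups:
                rg = resid[idx]
                s = rg.sum()
                num += (s * s - rg @ rg) / 2.0
                denom_pairs += len(idx) * (len(idx) - 1) // 2
            if denom_pairs == 0:
                alpha_new = 0.0
            else:
                alpha_new = num / (sigma2 * max(denom_pairs - k, 1))
            if not np.isfinite(alpha_new):
                return failure("non-finite working-correlation update")
            max_n = max(len(idx) for idx in groups)
            alpha_new = float(np.clip(alpha_new, -1.0 / max(max_n - 1, 1) + 1e-6, 0.999))
            vinv_blocks = [
                _exchangeable_vinv(len(idx), alpha_new, sigma2) for idx in groups
            ]
            lhs = np.zeros((k, k))
            rhs = np.zeros(k)
            for g, idx in enumerate(groups):
                XtV = Xa[idx].T @ vinv_blocks[g]
                lhs += XtV @ Xa[idx]
                rhs += XtV @ y[idx]
            beta_new = np.linalg.solve(lhs, rhs)
            if not np.all(np.isfinite(beta_new)):
                return failure("non-finite coefficient update")
            delta = np.max(np.abs(beta_new - beta))
            beta, alpha = beta_new, alpha_new
            if delta < tol:
                break
        else:
            return failure("iteration limit reached")

    resid = y - Xa @ beta
    cov = _sandwich(Xa, resid, groups, vinv_blocks,
                    bias_reduced=(cov_type == "bias_reduced"))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if not np.all(np.isfinite(se)):
        return failure("degenerate sandwich variance")
    # a perfect fit has zero residuals and hence zero sandwich variance:
    # coefficients are exact, Wald inference undefined
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * norm.sf(np.abs(z))
    return GeeResult(probe_id, terms, beta, se, z, p, True, len(labels), working)


@dataclass
class GeeResultTable:
    """Stacked per-probe results plus convergence bookkeeping."""

    table: pd.DataFrame
    terms: list[str]
    pgs_terms: list[str]
    working: str
    n_probes: int
    n_converged: int
    n_nonconverged: int
    messages: dict[str, str] = field(default_factory=dict)

    def to_long(self, converged_only: bool = True) -> pd.DataFrame:
        """Long format (probe_id, term, beta, se, z, p)."""
        tab = self.table
        if converged_only:
            tab = tab[tab["converged"].astype(bool)]
        records = []
        for term in self.terms:
            records.append(
                pd.DataFrame(
                    {
                        "probe_id": tab.index,
                        "term": term,
                        "beta": tab[f"{term}__beta"].to_numpy(),
                        "se": tab[f"{term}__se"].to_numpy(),
                        "z": tab[f"{term}__z"].to_numpy(),
                        "p": tab[f"{term}__p"].to_numpy(),
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def _fit_all_independence(Y: np.ndarray, Xa: np.ndarray, groups) -> tuple:
    """Vectorized OLS + cluster sandwich across all probes sharing one design."""
    XtX = Xa.T @ Xa
    binv = np.linalg.inv(XtX)
    B = np.linalg.solve(XtX, Xa.T @ Y)            # k x P
    R = Y - Xa @ B                                 # n x P
    A = np.stack([Xa[idx].T @ R[idx] for idx in groups])  # G x k x P
    meat = np.einsum("gkp,glp->pkl", A, A)         # P x k x k
    cov = np.einsum("ij,pjk,kl->pil", binv, meat, binv)
    var = np.einsum("pii->pi", cov)
    se = np.sqrt(np.maximum(var, 0.0))
    return B, se


def fit_all(
    meth: MethylMatrix,
    design: DesignMatrix,
    working: str = "independence",
) -> GeeResultTable:
    """Fit every probe against one shared design; report convergence counts.

    Probes whose fit fails (non-finite response, degenerate variance, or
    iteration failure under the exchangeable structure) are flagged
    non-converged: they stay in the table with NaN inference fields and are
    excluded by downstream thresholding.
    """
    if list(meth.values.index) != list(design.X.index):
        raise ValueError("methylation samples are not aligned with design rows")
    labels, groups = _cluster_slices(design.clusters)
    terms = list(design.X.columns)
    probe_ids = list(meth.values.columns)
    Y = meth.values.to_numpy(dtype=float)
    Xa = design.X.to_numpy(dtype=float)

    messages: dict[str, str] = {}
    rows: list[pd.Series] = []
    if working == "independence" and np.linalg.matrix_rank(Xa) == Xa.shape[1]:
        finite = np.all(np.isfinite(Y), axis=0)
        B = np.full((Xa.shape[1], Y.shape[1]), np.nan)
        SE = np.full_like(B, np.nan)
        if finite.any():
            Bf, SEf = _fit_all_independence(Y[:, finite], Xa, groups)
            B[:, finite] = Bf
            SE[:, finite.nonzero()[0]] = SEf.T
        ok = finite & np.all(np.isfinite(SE), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(ok & (SE > 0), B / SE, np.nan)
        P = 2.0 * norm.sf(np.abs(Z))
        data = {}
        for i, term in enumerate(terms):
            data[f"{term}__beta"] = np.where(ok, B[i], np.nan)
            data[f"{term}__se"] = np.where(ok, SE[i], np.nan)
            data[f"{term}__z"] = Z[i]
            data[f"{term}__p"] = P[i]
        table = pd.DataFrame(data, index=probe_ids)
        table["converged"] = ok
        for pid in np.asarray(probe_ids)[~ok]:
            messages[pid] = "non-finite response or degenerate variance"
    else:
        for j, pid in enumerate(probe_ids):
            res = fit_gee_probe(Y[:, j], design, probe_id=pid, working=working)
            rows.append(res.to_series())
            if not res.converged:
                messages[pid] = res.message
        table = pd.DataFrame(rows)
        table.index.name = "probe_id"

    n_conv = int(table["converged"].sum())
    n_total = len(table)
    logger.info(
        "fit_all: %d probes, %d successful analyses, %d non-converged (%s)",
        n_total, n_conv, n_total - n_conv, working,
    )
    return GeeResultTable(
        table=table,
        terms=terms,
        pgs_terms=design.pgs_terms,
        working=working,
        n_probes=n_total,
        n_converged=n_conv,
        n_nonconverged=n_total - n_conv,
        messages=messages,
    )
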