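"""Effective number of independent tests from the probe correlation spectrum.

Methylation probes are strongly correlated, so a Bonferroni correction by the
raw probe count is overly severe. Following Nyholt's matrix spectral
decomposition, the eigenvalue spectrum (lambda_1..lambda_M) of the probe x
probe Pearson correlation matrix summarizes that redundancy and the
effective number of independent tests is

    Meff = 1 + (M - 1) * (1 - Var(lambda) / M)

with Var the sample variance (denominator M - 1). Uncorrelated probes give
Var(lambda) = 0 and Meff = M; a rank-one correlation matrix gives Meff = 1.
The adjusted significance level is alpha / ceil(Meff) (rounding Meff up is
conservative). The Li & Ji refinement, Meff = sum_i [1(lambda_i >= 1)
+ frac(lambda_i)], is available as an option.

When there are far more probes than samples the M x M correlation matrix is
never formed: the nonzero spectrum equals that of the n x n cross-product of
the standardized data (dual matrix), and zeros are appended.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methprep import MethylMatrix


@dataclass
class MeffResult:
    m_probes: int
    eigenvalues: np.ndarray
    m_eff: float
    m_eff_int: int
    method: str

    def alpha(self, global_alpha: float = 0.05) -> float:
        return bonferroni_alpha(global_alpha, self.m_eff_int)


def _standardize_columns(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=0, ddof=1)
    tiny = np.finfo(float).eps * 100 * np.maximum(1.0, np.abs(v).max(axis=0))
    if np.any(sd <= tiny):
        raise ValueError(
            f"constant probe(s) at column index {np.flatnonzero(sd <= tiny)[:5].tolist()}: "
            "zero variance has no defined correlation"
        )
    return (v - v.mean(axis=0)) / sd


def correlation_eigenvalues(values: np.ndarray) -> np.ndarray:
    """Eigenvalues (descending) of the probe correlation matrix.

    Uses the direct M x M matrix when probes <= samples, otherwise the dual
    n x n matrix with zeros appended; the two paths agree on the nonzero
    spectrum. The spectrum sums to M (the trace of a correlation matrix).
    """
    v = np.asarray(values, dtype=float)
    n, m = v.shape
    if n < 3 or m < 2:
        raise ValueError("need at least 3 samples and 2 probes")
    z = _standardize_columns(v)
    if m <= n:
        corr = z.T @ z / (n - 1)
        eig = np.linalg.eigvalsh(corr)
    else:
        dual = z @ z.T / (n - 1)
        eig = np.concatenate([np.linalg.eigvalsh(dual), np.zeros(m - n)])
    eig = np.clip(eig, 0.0, None)
    return np.sort(eig)[::-1]


def meff_from_eigenvalues(eigenvalues: np.ndarray, method: str = "nyholt") -> float:
    lam = np.asarray(eigenvalues, dtype=float)
    m = len(lam)
    if method == "nyholt":
        var = lam.var(ddof=1)
        return 1.0 + (m - 1) * (1.0 - var / m)
    if method == "liji":
        return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    raise ValueError(f"unknown method {method!r}")


def effective_tests_nyholt(
    meth: MethylMatrix | pd.DataFrame | np.ndarray, method: str = "nyholt"
) -> MeffResult:
    """Effective number of independent tests for a samples x probes matrix."""
    if isinstance(meth, MethylMatrix):
        values = meth.values.to_numpy(dtype=float)
    elif isinstance(meth, pd.DataFrame):
        values = meth.to_numpy(dtype=float)
    else:
        values = np.asarray(meth, dtype=float)
    eig = correlation_eigenvalues(values)
    m_eff = meff_from_eigenvalues(eig, method=method)
    m_eff = float(min(max(m_eff, 1.0), values.shape[1]))
    return MeffResult(
        m_probes=values.shape[1],
        eigenvalues=eig,
        m_eff=m_eff,
        m_eff_int=int(math.ceil(m_eff - 1e-9)),
        method=method,
    )


def meff_from_correlation(corr: np.ndarray, method: str = "nyholt") -> float:
    """Meff straight from a correlation matrix (small problems / oracles)."""
    eig = np.linalg.eigvalsh(np.asarray(corr, dtype=float))
    return meff_from_eigenvalues(np.sort(eig)[::-1], method=method)


def bonferroni_alpha(global_alpha: float = 0.05, m_eff: float = 1) -> float:
    """Adjusted per-test significance level alpha / ceil(m_eff)."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    if not 0 < global_alpha < 1:
        raise ValueError("global_alpha must be in (0, 1)")
    return global_alpha / math.ceil(m_eff - 1e-9)
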