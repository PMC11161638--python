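"""Regression and multiple-testing helpers shared across the scans.

Every association in the package is an ordinary least squares fit of a score
on one predictor of interest plus lineage fixed effects.  The scans are
vectorised through the Frisch-Waugh-Lovell decomposition: the predictor and
the response are residualised against the covariate block once, and the
coefficient t-test for each predictor column follows from three inner
products with the degrees of freedom of the full design.  The resulting
betas, t statistics and p-values are identical to refitting the full OLS per
column (asserted against statsmodels in the test suite).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def lineage_design(lineage: pd.Series) -> np.ndarray:
    """Intercept + lineage dummy matrix with the smallest lineage dropped."""
    counts = lineage.value_counts()
    pivot = counts.index[-1]  # smallest count; ties resolved by value_counts
    levels = [lv for lv in counts.index if lv != pivot]
    n = len(lineage)
    X = np.ones((n, 1 + len(levels)))
    for j, lv in enumerate(levels):
        X[:, 1 + j] = (lineage == lv).to_numpy(dtype=float)
    return X


def residualize(M: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, int]:
    """Residuals of the columns of ``M`` against covariates ``C``.

    Returns the residual matrix and the rank of ``C``.
    """
    coef, _, rank, _ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef, int(rank)


def ols_scan(y: np.ndarray, X: np.ndarray, C: np.ndarray,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of ``y`` on each column of ``X`` with covariates ``C``.

    Parameters
    ----------
    y : (n,) response.
    X : (n, m) predictors of interest, one fit per column.
    C : (n, k) covariate block (should include an intercept column).

    Returns
    -------
    beta, t, p : (m,) arrays for the predictor coefficient.  Columns whose
    residualised predictor is (numerically) constant yield NaN.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    ey, rank = residualize(np.column_stack([y[:, None], X]), C)
    ry = ey[:, 0]
    rX = ey[:, 1:]
    sxx = np.einsum("ij,ij->j", rX, rX)
    sxy = rX.T @ ry
    syy = float(ry @ ry)
    df = n - rank - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    bad = (sxx <= max(n, 1e3) * np.finfo(float).eps * max(syy, 1.0)) | (df <= 0)
    t = np.where(bad, np.nan, t)
    beta = np.where(bad, np.nan, beta)
    p = 2 * stats.t.sf(np.abs(t), df) if df > 0 else np.full_like(t, np.nan)
    p = np.where(np.isnan(t), np.nan, p)
    return beta, t, p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs passed through)."""
    return _fdr(p, method="fdr_bh")


def by_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli q-values (BH inflated by the harmonic number)."""
    return _fdr(p, method="fdr_by")


def _fdr(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method=method)[1]
    return q
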