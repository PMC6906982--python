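"""Generalized least squares with a phylogenetic error covariance.

The estimator is the standard whitened form: with ``C = L L'`` (Cholesky),
solve OLS on ``L^{-1} y`` against ``L^{-1} X``.  The error scale sigma^2 is
profiled by maximum likelihood (``RSS_C / n``), the log-likelihood is that of
the multivariate normal ``N(X beta, sigma^2 C)``, and standard errors use the
small-sample ``n - p`` variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import AlignmentError, NumericalError

__all__ = ["GLSFit", "cholesky_factor", "gls_fit"]

#: Relative diagonal jitter applied when a covariance fails Cholesky.
_JITTER = 1e-10


def cholesky_factor(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of ``C``, adding ``1e-10 * trace`` jitter once
    if the matrix is numerically semidefinite."""
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        jitter = _JITTER * np.trace(C)
        try:
            return linalg.cholesky(C + jitter * np.eye(C.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalError(
                "covariance is not positive definite even after jitter"
            ) from exc


@dataclass
class GLSFit:
    """Raw output of one GLS solve (no model bookkeeping)."""

    params: np.ndarray          # beta-hat
    bse: np.ndarray             # standard errors (n - p denominator)
    sigma2_ml: float            # ML error scale RSS_C / n
    rss: float                  # whitened residual sum of squares
    llf: float                  # maximized log-likelihood (sigma^2 profiled)
    nobs: int
    df_resid: int
    normalized_cov_params: np.ndarray  # (X' C^-1 X)^-1
    resid: np.ndarray           # raw-scale residuals y - X beta
    degenerate: bool = False    # zero residual variance


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray | None = None,
    *,
    chol: np.ndarray | None = None,
) -> GLSFit:
    """Fit ``y = X beta + eps``, ``eps ~ N(0, sigma^2 C)`` by ML.

    Either ``C`` or its precomputed lower Cholesky factor ``chol`` must be
    given; passing ``chol`` lets calibration loops factor a fixed tree once.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise AlignmentError(f"y has {y.shape[0]} rows but X has {n}")
    if chol is None:
        if C is None:
            raise ValueError("provide C or chol")
        if C.shape != (n, n):
            raise AlignmentError("covariance dimension does not match data")
        chol = cholesky_factor(C)
    L = chol
    z = linalg.solve_triangular(L, y, lower=True)
    W = linalg.solve_triangular(L, X, lower=True)

    WtW = W.T @ W
    cond = np.linalg.cond(WtW)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(f"near-singular design (condition number {cond:.3g})")
    try:
        WtW_inv = linalg.inv(WtW)
    except linalg.LinAlgError as exc:
        raise NumericalError("singular design (collinear predictors)") from exc

    beta = WtW_inv @ (W.T @ z)
    resid_w = z - W @ beta
    rss = float(resid_w @ resid_w)
    sigma2_ml = rss / n
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))

    # zero residual variance (constant response or exact fit), judged
    # relative to the response scale
    degenerate = sigma2_ml <= 1e-20 * max(1.0, float(np.mean(y * y)))
    if degenerate:
        llf = np.inf
        bse = np.zeros(p)
    else:
        llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet_C + n)
        s2_unbiased = rss / (n - p) if n > p else np.nan
        bse = np.sqrt(np.diag(WtW_inv) * s2_unbiased)

    return GLSFit(
        params=beta,
        bse=bse,
        sigma2_ml=sigma2_ml,
        rss=rss,
        llf=llf,
        nobs=n,
        df_resid=n - p,
        normalized_cov_params=WtW_inv,
        resid=y - X @ beta,
        degenerate=degenerate,
    )
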