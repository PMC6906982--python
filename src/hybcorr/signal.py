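"""Maximum-likelihood phylogenetic signal (Pagel's lambda).

The model is a single-trait Brownian motion whose among-taxon covariance has
its off-diagonal entries scaled by ``lambda`` in [0, 1]; mean and rate are
profiled out analytically through GLS, and ``lambda`` is maximized by bounded
scalar search.  The likelihood-ratio test compares the fit against a star
phylogeny (``lambda = 0``) on one degree of freedom; the statistic is clamped
at zero (lambda-hat on the boundary can produce tiny negative differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, NumericalError
from .gls import cholesky_factor, gls_fit
from .trees import Phylogeny, PhyloCovariance, bm_covariance, lambda_transform

__all__ = ["PagelLambda", "PagelLambdaResults"]


def _align_response(y, taxa):
    if isinstance(y, pd.Series):
        missing = [t for t in taxa if t not in y.index]
        if missing:
            raise AlignmentError(f"response missing taxa: {missing[:5]}...")
        return y.loc[list(taxa)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(taxa):
        raise AlignmentError("response length does not match taxon count")
    return y


class PagelLambda:
    """Model: one trait on one tree, ``y ~ N(mu, sigma^2 C(lambda))``.

    Parameters
    ----------
    y : array-like or pandas Series
        Trait values; a Series is aligned to tip labels by index.
    phylogeny : Phylogeny or PhyloCovariance
        The tree (or a precomputed BM covariance) for the taxa with data.
    """

    def __init__(self, y, phylogeny):
        if isinstance(phylogeny, PhyloCovariance):
            self.bm = phylogeny
        elif isinstance(phylogeny, Phylogeny):
            self.bm = bm_covariance(phylogeny)
        else:
            raise TypeError("phylogeny must be Phylogeny or PhyloCovariance")
        self.taxa = self.bm.taxa
        self.y = _align_response(y, self.taxa)
        if len(self.taxa) < 4:
            raise AlignmentError("lambda estimation needs at least 4 taxa")

    def _profile_llf(self, lam: float) -> float:
        C = lambda_transform(self.bm, lam).matrix
        X = np.ones((len(self.y), 1))
        return gls_fit(self.y, X, C).llf

    def fit(self, xtol: float = 1e-8) -> "PagelLambdaResults":
        n = len(self.y)
        if np.ptp(self.y) == 0.0:
            # No variance: lambda unidentifiable.
            return PagelLambdaResults(
                lambda_=0.0, sigma2=0.0, mu=float(self.y[0]),
                llf=np.nan, llf_star=np.nan, lrt=0.0, pvalue=1.0,
                nobs=n, degenerate=True,
            )
        res = optimize.minimize_scalar(
            lambda lam: -self._profile_llf(lam),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": xtol},
        )
        if not res.success:
            raise NumericalError(f"lambda optimizer failed: {res.message}")
        # Bounded search can stall just inside the boundary; the boundary
        # values are legitimate candidates for the maximum.
        candidates = {float(res.x): -res.fun}
        for lam in (0.0, 1.0):
            candidates[lam] = self._profile_llf(lam)
        lam_hat, llf_hat = max(candidates.items(), key=lambda kv: kv[1])
        llf_star = candidates[0.0]

        C = lambda_transform(self.bm, lam_hat).matrix
        full = gls_fit(self.y, np.ones((n, 1)), C)
        lrt = max(0.0, 2.0 * (llf_hat - llf_star))
        pvalue = float(stats.chi2.sf(lrt, df=1))
        return PagelLambdaResults(
            lambda_=lam_hat,
            sigma2=full.sigma2_ml,
            mu=float(full.params[0]),
            llf=llf_hat,
            llf_star=llf_star,
            lrt=lrt,
            pvalue=pvalue,
            nobs=n,
            degenerate=False,
        )


@dataclass
class PagelLambdaResults:
    """ML estimate of Pagel's lambda with its star-phylogeny LRT."""

    lambda_: float
    sigma2: float
    mu: float
    llf: float
    llf_star: float
    lrt: float
    pvalue: float
    nobs: int
    degenerate: bool = False
    df: int = 1

    def summary(self) -> str:
        lines = [
            "Pagel's lambda (ML)",
            "-" * 34,
            f"n taxa            {self.nobs:>12d}",
            f"lambda            {self.lambda_:>12.4f}",
            f"sigma^2 (ML)      {self.sigma2:>12.6g}",
            f"root mean         {self.mu:>12.6g}",
            f"logL              {self.llf:>12.4f}",
            f"logL (lambda=0)   {self.llf_star:>12.4f}",
            f"LRT chi^2 (1 df)  {self.lrt:>12.4f}",
            f"P-value           {self.pvalue:>12.4g}",
        ]
        if self.degenerate:
            lines.append("WARNING: zero trait variance; lambda unidentifiable")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "n": self.nobs,
            "lambda": self.lambda_,
            "chi_square": self.lrt,
            "df": self.df,
            "p_value": self.pvalue,
        }
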