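"""Phylogenetic generalized least squares regression under BM, OU and EB.

:class:`PGLS` regresses a response on one or more predictors (intercept
added automatically) with error covariance proportional to a tree-derived
matrix.  Under BM the covariance is fixed; under OU and EB the single
covariance parameter (``alpha`` or ``r``) is profiled by bounded ML with
bounds tied to the tree depth ``T`` (``alpha`` in ``[1e-8, 50/T]``, ``r`` in
``[-10/T, 0]``).  Model fit is summarized by ML log-likelihood, AIC/BIC
(parameter count = regression coefficients + error scale + any profiled
covariance parameter), coefficient t-tests on ``n - p`` degrees of freedom,
and a deviance-based adjusted R-squared measured against the intercept-only
GLS fit under the same covariance.

Also here: AIC/BIC model comparison with the "report BM when all models are
within 2 AIC" convention, Benjamini-Hochberg FDR flags, and plain Pearson
correlations for uncorrected reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, NumericalError
from .gls import GLSFit, cholesky_factor, gls_fit
from .trees import (
    Phylogeny,
    PhyloCovariance,
    bm_covariance,
    eb_transform,
    ou_transform,
)

__all__ = [
    "PGLS",
    "PGLSResults",
    "ModelComparison",
    "compare_models",
    "adjusted_r2",
    "benjamini_hochberg",
    "pearson_with_p",
    "RawCorrelation",
]

MODELS = ("BM", "OU", "EB")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """``1 - (1 - R^2)(n - 1)/(n - p - 1)``; may be negative."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)


class PGLS:
    """Phylogenetic regression model (statsmodels-style: ``fit`` returns results).

    Parameters
    ----------
    y : Series or array
        Response, aligned by index to tip labels when a Series.
    x : Series, DataFrame or array
        Predictor(s); an intercept column is always prepended.
    phylogeny : Phylogeny
        Tree covering exactly the analysis taxa (prune beforehand).
    model : {"BM", "OU", "EB"}
    """

    def __init__(self, y, x, phylogeny: Phylogeny, model: str = "BM"):
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.model = model
        self.phylogeny = phylogeny
        self.bm = bm_covariance(phylogeny)
        self.taxa = self.bm.taxa
        self.y = self._align(y)
        X, names = self._design(x)
        self.exog = X
        self.exog_names = names
        if self.exog.shape[0] < self.exog.shape[1] + 1:
            raise AlignmentError("more parameters than taxa")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, predictors, phylogeny: Phylogeny,
        model: str = "BM",
    ) -> "PGLS":
        """Build from a taxon-indexed DataFrame, dropping incomplete rows
        and pruning the tree to the complete cases."""
        if isinstance(predictors, str):
            predictors = [predictors]
        cols = [response, *predictors]
        sub = data.loc[data.index.intersection(phylogeny.tip_labels), cols].dropna()
        if len(sub) < 5:
            raise AlignmentError(
                f"only {len(sub)} complete-case taxa for {response} ~ {predictors}; need >= 5"
            )
        pruned = phylogeny.prune_to(sub.index)
        return cls(sub[response], sub[predictors], pruned, model=model)

    def _align(self, y):
        if isinstance(y, pd.Series):
            missing = [t for t in self.taxa if t not in y.index]
            if missing:
                raise AlignmentError(f"response missing taxa: {missing[:5]}")
            return y.loc[list(self.taxa)].to_numpy(dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(self.taxa):
            raise AlignmentError("response length does not match tree")
        return y

    def _design(self, x):
        if isinstance(x, pd.DataFrame):
            vals = x.loc[list(self.taxa)].to_numpy(dtype=float)
            names = list(x.columns)
        elif isinstance(x, pd.Series):
            vals = x.loc[list(self.taxa)].to_numpy(dtype=float)[:, None]
            names = [x.name or "x"]
        else:
            vals = np.asarray(x, dtype=float)
            if vals.ndim == 1:
                vals = vals[:, None]
            names = [f"x{i}" for i in range(vals.shape[1])]
        n = len(self.taxa)
        if vals.shape[0] != n:
            raise AlignmentError("predictor rows do not match tree")
        return np.column_stack([np.ones(n), vals]), ["const", *names]

    # -- covariance under each model --------------------------------------

    def _cov_at(self, param: float | None) -> np.ndarray:
        if self.model == "BM":
            return self.bm.matrix
        if self.model == "OU":
            return ou_transform(self.phylogeny, param, bm=self.bm).matrix
        return eb_transform(self.phylogeny, param, bm=self.bm).matrix

    def _param_bounds(self) -> tuple[float, float]:
        T = float(self.bm.matrix.diagonal().max())
        if self.model == "OU":
            return (1e-8, 50.0 / T)
        return (-10.0 / T, 0.0)

    def fit(self, xtol: float = 1e-8) -> "PGLSResults":
        if self.model == "BM":
            cov_param = None
            C = self.bm.matrix
            raw = gls_fit(self.y, self.exog, C)
        else:
            lo, hi = self._param_bounds()

            def nll(p: float) -> float:
                return -gls_fit(self.y, self.exog, self._cov_at(p)).llf

            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": xtol}
            )
            if not res.success:
                raise NumericalError(f"{self.model} profile optimizer failed: {res.message}")
            # boundary values compete with the interior optimum
            cands = {float(res.x): -res.fun, lo: -nll(lo), hi: -nll(hi)}
            cov_param = max(cands, key=cands.get)
            C = self._cov_at(cov_param)
            raw = gls_fit(self.y, self.exog, C)

        n, p_tot = self.exog.shape
        null = gls_fit(self.y, np.ones((n, 1)), C)
        r2 = 1.0 - raw.rss / null.rss if null.rss > 0 else 1.0
        n_pred = p_tot - 1
        adj = adjusted_r2(r2, n, n_pred)
        k = p_tot + 1 + (0 if cov_param is None else 1)

        if raw.degenerate:
            tvals = np.full(p_tot, np.nan)
            pvals = np.full(p_tot, np.nan)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = raw.params / raw.bse
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df=raw.df_resid)

        return PGLSResults(
            model=self.model,
            exog_names=self.exog_names,
            params=pd.Series(raw.params, index=self.exog_names),
            bse=pd.Series(raw.bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            sigma2=raw.sigma2_ml,
            llf=raw.llf,
            nobs=n,
            k_params=k,
            cov_param=cov_param,
            rsquared=r2,
            rsquared_adj=adj,
            degenerate=raw.degenerate,
        )


@dataclass
class PGLSResults:
    """Coefficients, uncertainty and fit diagnostics of one PGLS regression."""

    model: str
    exog_names: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    llf: float
    nobs: int
    k_params: int
    cov_param: float | None
    rsquared: float
    rsquared_adj: float
    degenerate: bool = False

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def slope_name(self) -> str:
        return self.exog_names[1]

    def summary(self) -> str:
        head = [
            f"PGLS regression ({self.model} covariance)",
            "=" * 58,
            f"n taxa: {self.nobs}    logL: {self.llf:.4f}    "
            f"AIC: {self.aic:.2f}    BIC: {self.bic:.2f}",
            f"adj. R^2: {self.rsquared_adj:.4f}    sigma^2 (ML): {self.sigma2:.6g}",
        ]
        if self.cov_param is not None:
            pname = "alpha" if self.model == "OU" else "r"
            head.append(f"profiled {pname}: {self.cov_param:.6g}")
        head.append("-" * 58)
        head.append(f"{'':<16}{'coef':>10}{'se':>10}{'t':>9}{'P>|t|':>11}")
        for name in self.exog_names:
            head.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>11.4g}"
            )
        return "\n".join(head)

    def to_row(self) -> dict:
        name = self.slope_name
        return {
            "model": self.model,
            "estimate": float(self.params[name]),
            "se": float(self.bse[name]),
            "t": float(self.tvalues[name]),
            "p_value": float(self.pvalues[name]),
            "adjusted_r2": self.rsquared_adj,
            "logL": self.llf,
            "AIC": self.aic,
            "BIC": self.bic,
            "n": self.nobs,
        }


@dataclass
class ModelComparison:
    """AIC/BIC ranking across covariance models for one regression."""

    table: pd.DataFrame
    within_2_aic: bool
    representative: str

    def summary(self) -> str:
        note = (
            "all models within 2 AIC; BM reported as representative"
            if self.within_2_aic
            else f"representative: {self.representative} (AIC best)"
        )
        return self.table.to_string() + "\n" + note


def compare_models(fits: dict[str, PGLSResults]) -> ModelComparison:
    """Rank fitted covariance models by AIC; BM is the representative model
    whenever every model lies within 2 AIC of the best."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fitted models to compare")
    rows = []
    for name, fit in fits.items():
        rows.append(
            {"model": name, "logL": fit.llf, "k": fit.k_params, "AIC": fit.aic, "BIC": fit.bic}
        )
    tab = pd.DataFrame(rows).set_index("model")
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    tab["dBIC"] = tab["BIC"] - tab["BIC"].min()
    tab = tab.sort_values("AIC")
    within = bool((tab["dAIC"] <= 2.0).all())
    if within and "BM" in tab.index:
        representative = "BM"
    else:
        representative = str(tab.index[0])
    return ModelComparison(table=tab, within_2_aic=within, representative=representative)


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class RawCorrelation:
    """Pearson correlation with its two-sided t-test (no phylogenetic correction)."""

    r: float
    p_value: float
    n: int
    degenerate: bool = False


def pearson_with_p(x, y) -> RawCorrelation:
    """Pairwise-complete Pearson r with p from ``t = r sqrt((n-2)/(1-r^2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RawCorrelation(r=np.nan, p_value=np.nan, n=n, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return RawCorrelation(r=float(r), p_value=float(p), n=n)
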