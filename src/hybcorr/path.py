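"""Phylogenetic path analysis over candidate DAGs.

Each candidate model is a directed acyclic graph over traits (here typically
woodiness W, perenniality P and a log hybridization metric H).  A model's
testable content is its d-separation basis set: one conditional-independence
claim per non-adjacent ordered pair ``(x, y)`` (x before y topologically),
conditioning on the union of the parents of x and of y.  Each claim is
tested by a BM-covariance PGLS of ``y`` on the conditioning set plus ``x``
(two-sided p of x's coefficient); the claims combine into Fisher's
``C = -2 sum(ln p)``, chi-square with ``2k`` degrees of freedom under the
model.  Candidates are ranked by ``CICc = C + 2 q n/(n - 1 - q)`` with the
parameter count ``q`` = directed edges + nodes, and the best model's path
coefficients come from standardized PGLS fits of each node on its parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ValidationError
from .gls import cholesky_factor, gls_fit
from .trees import Phylogeny, bm_covariance

__all__ = [
    "PathModel",
    "IndependenceClaim",
    "basis_set",
    "fishers_c",
    "cicc",
    "default_candidate_set",
    "PathAnalysis",
    "PathModelFit",
    "PathAnalysisResults",
]

#: Claims' p-values are floored here before logs to keep Fisher's C finite.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class PathModel:
    """A named DAG: nodes are trait labels, edges are directed causal paths."""

    name: str
    edges: tuple[tuple[str, str], ...]
    nodes: tuple[str, ...] = ()

    def __post_init__(self):
        nodes = list(dict.fromkeys(self.nodes))
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop {a}->{b} in model {self.name}")
            for v in (a, b):
                if v not in nodes:
                    nodes.append(v)
        if len(set(self.edges)) != len(self.edges):
            raise ValidationError(f"duplicate edges in model {self.name}")
        object.__setattr__(self, "nodes", tuple(nodes))
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError(f"model {self.name} is cyclic")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def q(self, mode: str = "edges+nodes") -> int:
        """CICc parameter count; default counts edges plus nodes."""
        if mode == "edges+nodes":
            return len(self.edges) + len(self.nodes)
        if mode == "edges":
            return len(self.edges)
        raise ValueError(f"unknown q mode {mode!r}")


@dataclass(frozen=True)
class IndependenceClaim:
    """``x`` independent of ``y`` given ``given`` (ordered, deterministic)."""

    x: str
    y: str
    given: tuple[str, ...]

    def __str__(self) -> str:
        cond = ", ".join(self.given) if self.given else "-"
        return f"{self.x} _||_ {self.y} | {{{cond}}}"


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """Directional-separation basis: one claim per non-adjacent pair.

    Pairs are oriented so ``x`` precedes ``y`` in a lexicographic topological
    order; the conditioning set is ``parents(x) | parents(y)``.  Output order
    is deterministic (sorted by the pair).
    """
    g = model.graph()
    topo = list(nx.lexicographical_topological_sort(g))
    pos = {v: i for i, v in enumerate(topo)}
    claims = []
    for i, x in enumerate(topo):
        for y in topo[i + 1 :]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            given = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(IndependenceClaim(x=x, y=y, given=tuple(sorted(given))))
    claims.sort(key=lambda c: (pos[c.x], pos[c.y]))
    return claims


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C over claim p-values: ``(C, df, upper-tail chi^2 p)``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, P_FLOOR)
    C = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return C, df, float(stats.chi2.sf(C, df=df))


def cicc(C: float, q: int, n: int) -> float:
    """C-statistic information criterion ``C + 2 q n/(n - 1 - q)``."""
    if n <= q + 1:
        raise ValueError(f"CICc undefined for n={n}, q={q} (need n > q + 1)")
    return C + 2.0 * q * n / (n - 1.0 - q)


def default_candidate_set(
    w: str = "woodiness", p: str = "perenniality", h: str = "hybridization"
) -> list[PathModel]:
    """Five candidate DAGs linking woodiness, perenniality and hybridization."""
    return [
        PathModel("m1_chain_wph", ((w, p), (p, h))),
        PathModel("m2_chain_pwh", ((p, w), (w, h))),
        PathModel("m3_wph_plus_wh", ((w, p), (p, h), (w, h))),
        PathModel("m4_pwh_plus_ph", ((p, w), (w, h), (p, h))),
        PathModel("m5_both_direct", ((w, p), (w, h), (p, h))),
    ]


@dataclass
class PathModelFit:
    """One candidate DAG's d-separation test results and path coefficients."""

    model: PathModel
    claims: list[tuple[IndependenceClaim, float]]
    c_stat: float
    df: int
    p_value: float
    q: int
    cicc: float
    coefficients: pd.DataFrame  # columns: source, target, estimate, se
    nobs: int

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.model.edges


@dataclass
class PathAnalysisResults:
    """CICc-ranked candidate fits; ``fits[0]`` is the best model."""

    fits: list[PathModelFit]
    nobs: int

    @property
    def best(self) -> PathModelFit:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": f.model.name,
                "C": f.c_stat,
                "df": f.df,
                "p_value": f.p_value,
                "q": f.q,
                "CICc": f.cicc,
                "dCICc": f.cicc - self.fits[0].cicc,
                "n": f.nobs,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        out = ["Phylogenetic path analysis (BM covariance)", "=" * 60]
        out.append(self.to_frame().to_string(index=False))
        out.append("")
        best = self.best
        out.append(f"Best model: {best.model.name}; standardized path coefficients:")
        out.append(best.coefficients.to_string(index=False))
        return "\n".join(out)


class PathAnalysis:
    """Fit and rank candidate path models on a taxon-indexed trait table.

    All claims and coefficients are evaluated on the common complete-case
    taxon set across every variable of every candidate, so CICc values are
    comparable; variables are z-scored on that set before fitting.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        phylogeny: Phylogeny,
        models: list[PathModel] | None = None,
        q_mode: str = "edges+nodes",
        standardize: bool = True,
    ):
        self.models = list(models) if models is not None else default_candidate_set()
        if not self.models:
            raise ValidationError("no candidate models supplied")
        variables = sorted({v for m in self.models for v in m.nodes})
        missing = [v for v in variables if v not in data.columns]
        if missing:
            raise ValidationError(f"data lacks path variables: {missing}")
        shared = data.loc[data.index.intersection(phylogeny.tip_labels), variables].dropna()
        if len(shared) < 5:
            raise AlignmentError(
                f"only {len(shared)} complete-case taxa shared with the tree; need >= 5"
            )
        self.phylogeny = (
            phylogeny
            if set(shared.index) == set(phylogeny.tip_labels)
            else phylogeny.prune_to(shared.index)
        )
        bm = bm_covariance(self.phylogeny)
        self.taxa = bm.taxa
        self._chol = cholesky_factor(bm.matrix)
        frame = shared.loc[list(self.taxa)]
        if standardize:
            frame = (frame - frame.mean()) / frame.std(ddof=1)
        self.data = frame
        self.q_mode = q_mode

    # -- single pieces -----------------------------------------------------

    def test_claim(self, claim: IndependenceClaim) -> float:
        """p-value of x's coefficient in PGLS of y on (conditioning set, x)."""
        n = len(self.taxa)
        cols = [*claim.given, claim.x]
        X = np.column_stack([np.ones(n), self.data[cols].to_numpy()])
        fit = gls_fit(self.data[claim.y].to_numpy(), X, chol=self._chol)
        i = X.shape[1] - 1  # x is the last column
        if fit.degenerate:
            return 0.0
        t = fit.params[i] / fit.bse[i]
        return float(2.0 * stats.t.sf(abs(t), df=fit.df_resid))

    def _coefficients(self, model: PathModel) -> pd.DataFrame:
        rows = []
        g = model.graph()
        for node in model.nodes:
            parents = sorted(g.predecessors(node))
            if not parents:
                continue
            n = len(self.taxa)
            X = np.column_stack([np.ones(n), self.data[parents].to_numpy()])
            fit = gls_fit(self.data[node].to_numpy(), X, chol=self._chol)
            for j, par in enumerate(parents, start=1):
                rows.append(
                    {
                        "source": par,
                        "target": node,
                        "estimate": float(fit.params[j]),
                        "se": float(fit.bse[j]),
                    }
                )
        return pd.DataFrame(rows, columns=["source", "target", "estimate", "se"])

    def fit_model(self, model: PathModel) -> PathModelFit:
        claims = basis_set(model)
        tested = [(c, self.test_claim(c)) for c in claims]
        C, df, p = fishers_c([pv for _, pv in tested])
        q = model.q(self.q_mode)
        value = cicc(C, q, len(self.taxa))
        return PathModelFit(
            model=model,
            claims=tested,
            c_stat=C,
            df=df,
            p_value=p,
            q=q,
            cicc=value,
            coefficients=self._coefficients(model),
            nobs=len(self.taxa),
        )

    def fit(self) -> PathAnalysisResults:
        fits = [self.fit_model(m) for m in self.models]
        fits.sort(key=lambda f: (f.cicc, f.model.n_edges, f.model.name))
        return PathAnalysisResults(fits=fits, nobs=len(self.taxa))
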