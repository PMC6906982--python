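"""Phylogeny ingestion and among-taxon covariance construction.

A :class:`Phylogeny` wraps a rooted, branch-length-bearing ``dendropy`` tree
with unique tip labels.  From it the module builds the among-taxon covariance
matrices used by generalized least squares:

* Brownian motion (BM): ``C[i, j]`` equals the branch length shared by the
  root-to-tip paths of taxa *i* and *j* (the depth of their most recent
  common ancestor); the diagonal holds root-to-tip depths.
* Pagel's lambda: off-diagonal entries of the BM matrix scaled by
  ``lam`` in [0, 1] (``lam = 0`` is a star phylogeny, ``lam = 1`` pure BM).
* Ornstein-Uhlenbeck (OU, stationary Hansen form) with pull strength
  ``alpha >= 0`` on an ultrametric tree of depth ``T``::

      C[i, j] = exp(-2 alpha (T - t_ij)) (1 - exp(-2 alpha t_ij)) / (2 alpha)

  where ``t_ij`` is the BM shared path length; the ``alpha -> 0`` limit is
  the BM matrix and is taken analytically below ``alpha = 1e-9``.
* Early burst (EB) with rate-decay parameter ``r <= 0``::

      C[i, j] = (exp(r t_ij) - 1) / r,   r = 0  ->  BM.

Polytomies are supported natively and never randomly resolved.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ModelAssumptionError, TreeError

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "bm_covariance",
    "lambda_transform",
    "ou_transform",
    "eb_transform",
]

#: Parameter below which OU/EB transforms fall back to the analytic BM limit.
_SMALL_PARAM = 1e-9

#: Relative tip-depth spread tolerated when a model requires ultrametricity.
ULTRAMETRIC_RTOL = 1e-6


class Phylogeny:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        newick = newick.strip()
        if not newick.endswith(";"):
            raise TreeError(
                "malformed Newick: missing terminating ';' at position %d" % len(newick)
            )
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise TreeError(
                    f"missing branch length on edge above {node.taxon.label if node.taxon else 'an internal node'}"
                )
            if node.edge.length < 0:
                raise TreeError("negative branch length")

    # -- basic properties --------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                # A pruned tree keeps the removed basal path as the seed
                # node's edge length; including it preserves original depths.
                node._hc_depth = node.edge.length or 0.0
            else:
                node._hc_depth = node.parent_node._hc_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                out[node.taxon.label] = node._hc_depth
        return out

    @property
    def depth(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.depths().values()))
        dmax = d.max()
        if dmax == 0:
            return True
        return (d.max() - d.min()) / dmax <= rtol

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    # -- pruning -----------------------------------------------------------

    def prune_to(self, keep) -> "Phylogeny":
        """Induced subtree on ``keep``; collapsed unifurcations sum lengths.

        Root-to-tip depths of retained tips are unchanged.
        """
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError(f"cannot prune to fewer than 2 taxa (got {len(keep)})")
        if keep == set(self.tip_labels):
            return Phylogeny(self._tree.clone(depth=1))
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        # dendropy can leave a unifurcation at the root; fold its edge away so
        # retained tip depths include the retained root edge length.
        clone.suppress_unifurcations()
        return Phylogeny(clone)


def read_newick(path) -> Phylogeny:
    """Read a Newick file (branch lengths required) into a :class:`Phylogeny`."""
    return Phylogeny.read(path)


@dataclass
class PhyloCovariance:
    """An among-taxon covariance matrix tied to an ordered taxon list."""

    taxa: tuple[str, ...]
    matrix: np.ndarray
    model: str = "BM"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance shape does not match taxon count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance is not symmetric")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def subset(self, taxa) -> "PhyloCovariance":
        """Row/column selection to an ordered subset of taxa."""
        index = {t: i for i, t in enumerate(self.taxa)}
        try:
            idx = np.array([index[t] for t in taxa])
        except KeyError as exc:
            raise KeyError(f"taxon {exc} not in covariance") from exc
        return PhyloCovariance(
            taxa=tuple(taxa),
            matrix=self.matrix[np.ix_(idx, idx)],
            model=self.model,
            params=dict(self.params),
        )


def _node_depths_and_tip_index(phylo: Phylogeny):
    tree = phylo.tree
    tips = phylo.tip_labels
    tip_pos = {label: i for i, label in enumerate(tips)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._hc_depth = node.edge.length or 0.0
        else:
            node._hc_depth = node.parent_node._hc_depth + (node.edge.length or 0.0)
    return tips, tip_pos


def bm_covariance(phylo: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-tip path lengths.

    Zero-length terminal branches make the matrix singular (identical rows);
    they trigger a warning and a diagonal jitter of ``1e-8 * tree depth`` on
    the affected tips.
    """
    tips, tip_pos = _node_depths_and_tip_index(phylo)
    n = len(tips)
    C = np.zeros((n, n))
    # Postorder: each node yields the tip-index set below it; tips in
    # different child subtrees share exactly this node's depth.
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_pos[node.taxon.label]
            node._hc_tips = np.array([i])
            C[i, i] = node._hc_depth
        else:
            groups = [child._hc_tips for child in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = node._hc_depth
                    C[np.ix_(groups[b], groups[a])] = node._hc_depth
            node._hc_tips = np.concatenate(groups)
    zero_tips = [
        tip_pos[leaf.taxon.label]
        for leaf in phylo.tree.leaf_node_iter()
        if (leaf.edge.length or 0.0) == 0.0
    ]
    if zero_tips:
        warnings.warn(
            "zero-length terminal branch(es): BM covariance is singular; "
            "adding diagonal jitter",
            stacklevel=2,
        )
        C[zero_tips, zero_tips] += 1e-8 * C.diagonal().max()
    return PhyloCovariance(taxa=tips, matrix=C, model="BM", params={})


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal entries by Pagel's lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.matrix * lam
    np.fill_diagonal(C, cov.matrix.diagonal())
    return PhyloCovariance(
        taxa=cov.taxa, matrix=C, model="lambda", params={"lambda": lam}
    )


def _require_ultrametric(phylo: Phylogeny, model: str) -> float:
    if not phylo.is_ultrametric():
        raise ModelAssumptionError(
            f"{model} covariance requires an ultrametric tree "
            f"(relative tip-depth spread > {ULTRAMETRIC_RTOL:g})"
        )
    return phylo.depth


def ou_transform(
    phylo: Phylogeny, alpha: float, bm: PhyloCovariance | None = None
) -> PhyloCovariance:
    """Stationary Ornstein-Uhlenbeck covariance on an ultrametric tree."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    T = _require_ultrametric(phylo, "OU")
    if bm is None:
        bm = bm_covariance(phylo)
    t = bm.matrix
    if alpha < _SMALL_PARAM:
        C = t.copy()
    else:
        C = np.exp(-2.0 * alpha * (T - t)) * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    return PhyloCovariance(taxa=bm.taxa, matrix=C, model="OU", params={"alpha": alpha})


def eb_transform(
    phylo: Phylogeny, r: float, bm: PhyloCovariance | None = None
) -> PhyloCovariance:
    """Early-burst covariance: rate decays as exp(r * time), r <= 0."""
    if r > 0:
        raise ValueError(f"early-burst rate parameter must be <= 0, got {r}")
    if bm is None:
        bm = bm_covariance(phylo)
    t = bm.matrix
    if abs(r) < _SMALL_PARAM:
        C = t.copy()
    else:
        C = np.expm1(r * t) / r
    return PhyloCovariance(taxa=bm.taxa, matrix=C, model="EB", params={"r": r})
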