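"""Synthetic phylogenies, trait tables, and flora-style hybrid counts.

The generator stands in for the regional-flora and megatree inputs of the
real analysis so every pipeline stage can be exercised with known ground
truth:

* trees are pure-birth (Yule) and hence ultrametric;
* taxon-level trait scores evolve as correlated Brownian motion with a
  per-trait Pagel's lambda, and bounded scores are squashed to (0, 1) by the
  logistic function;
* hybrid counts follow a log-linear model: a genus with ``n_i`` nonhybrid
  species (shifted negative binomial, minimum 2 — genus sizes are heavily
  right-skewed) produces ``H_i ~ Poisson(mu_i)`` hybrids with::

      ln mu_i = beta0 + sum_t beta_t z_ti + ln(n_i (n_i - 1) / 2) + eps_i

  where ``z`` are standardized trait scores and ``eps`` is Brownian noise on
  the same tree.  The pair-count offset makes the planted effects act on
  hybridization propensity rather than raw counts.  Counts are then
  scattered over several "floras" in proportion to each flora's share of the
  genus's species.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .flora import FLORA_COLUMNS
from .gls import cholesky_factor
from .trees import Phylogeny, bm_covariance, lambda_transform

__all__ = [
    "TraitSpec",
    "CountModel",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_traits",
    "simulate_hybrid_counts",
    "simulate_path_dataset",
    "make_benchmark_suite",
    "SCENARIOS",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed=None, prefix: str = "t"
) -> Phylogeny:
    """Pure-birth ultrametric tree with exactly ``n_taxa`` tips.

    Waiting times between speciation events are exponential with rate
    ``k * birth_rate`` for ``k`` extant lineages; a final waiting time after
    the last split keeps terminal branches positive.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    k = 2
    while k < n_taxa:
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, _birth = active.pop(idx)
        node.edge.length = t - _birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
        k += 1
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for i, (node, birth) in enumerate(active, start=1):
        node.edge.length = t - birth
        node.taxon = tns.new_taxon(label=f"{prefix}{i}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# traits


@dataclass(frozen=True)
class TraitSpec:
    """Ground truth for one simulated trait."""

    name: str
    lam: float = 1.0        # Pagel's lambda in [0, 1]
    sigma2: float = 1.0     # BM rate per unit branch length
    mean: float = 0.0       # root state (on the latent scale)
    bounded: bool = False   # squash to (0, 1) by the logistic function

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError(f"lambda for {self.name} outside [0, 1]")
        if self.sigma2 < 0:
            raise ValidationError(f"negative sigma^2 for {self.name}")


def simulate_traits(
    tree: Phylogeny,
    specs: list[TraitSpec],
    correlation: np.ndarray | None = None,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Correlated lambda-BM trait scores for every tip.

    ``correlation`` couples the per-unit-time evolutionary deviates of the
    traits (identity if omitted); with equal lambdas this is exactly the
    Kronecker product of the trait correlation and the lambda-transformed
    tree covariance.  Bounded traits are reported as ``logistic(latent)``.
    """
    rng = _rng(seed)
    n = tree.n_tips
    T = len(specs)
    if correlation is None:
        correlation = np.eye(T)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (T, T):
        raise ValidationError("correlation matrix shape does not match trait count")
    if not np.allclose(correlation, correlation.T):
        raise ValidationError("trait correlation matrix must be symmetric")
    try:
        A = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("trait correlation matrix must be positive definite") from exc

    bm = bm_covariance(tree)
    Z = rng.standard_normal((n, T)) @ A.T  # rows ~ N(0, R)
    cols = {}
    for j, spec in enumerate(specs):
        if spec.sigma2 == 0.0:
            latent = np.full(n, spec.mean)
        else:
            L = cholesky_factor(lambda_transform(bm, spec.lam).matrix)
            latent = spec.mean + np.sqrt(spec.sigma2) * (L @ Z[:, j])
        cols[spec.name] = 1.0 / (1.0 + np.exp(-latent)) if spec.bounded else latent
    traits = pd.DataFrame(cols, index=list(bm.taxa))
    traits.index.name = "taxon"
    truth = {
        "traits": [asdict(s) for s in specs],
        "correlation": correlation.tolist(),
    }
    return traits, truth


# ---------------------------------------------------------------------------
# hybrid counts


@dataclass(frozen=True)
class CountModel:
    """Log-linear generating model for flora hybrid counts.

    ``beta0`` sets the baseline log propensity (as a fraction of possible
    pairs): the default ``exp(-3.5) ~= 3%`` matches the few-percent mean
    propensities typical of flora compilations.  ``effects`` maps trait
    names to log-rate slopes per standard deviation of the trait score.
    """

    beta0: float = -3.5
    effects: dict = field(default_factory=dict)
    noise_scale: float = 0.5          # sd of the Brownian log-rate noise
    n_floras: int = 8
    nb_mean: float = 8.0              # mean genus size (species), min 2
    nb_dispersion: float = 1.0        # negative binomial shape (smaller = heavier tail)
    unspecified_fraction: float = 0.0
    intergeneric_rate: float = 0.0    # expected intergeneric halves per genus

    def __post_init__(self):
        if self.n_floras < 1:
            raise ValidationError("need at least one flora")
        if self.nb_mean < 2:
            raise ValidationError("mean genus size must be >= 2")


def simulate_hybrid_counts(
    tree: Phylogeny,
    traits: pd.DataFrame,
    count_model: CountModel = CountModel(),
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-(genus, flora) count records from the log-linear model."""
    rng = _rng(seed)
    taxa = list(traits.index)
    missing = set(taxa) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"traits contain taxa absent from the tree: {sorted(missing)[:5]}")
    n_taxa = len(taxa)
    cm = count_model

    # genus sizes: 2 + negative binomial
    extra_mean = cm.nb_mean - 2.0
    if extra_mean > 0:
        shape = cm.nb_dispersion
        p = shape / (shape + extra_mean)
        sizes = 2 + rng.negative_binomial(shape, p, size=n_taxa)
    else:
        sizes = np.full(n_taxa, 2, dtype=int)
    pairs = sizes * (sizes - 1) / 2.0

    # linear predictor on standardized trait scores
    lin = np.full(n_taxa, cm.beta0, dtype=float)
    for name, beta in cm.effects.items():
        if name not in traits.columns:
            raise ValidationError(f"effect on unknown trait {name!r}")
        col = traits[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n_taxa)
        lin += beta * z

    if cm.noise_scale > 0:
        bm = bm_covariance(tree.prune_to(taxa) if set(taxa) != set(tree.tip_labels) else tree)
        order = [bm.taxa.index(t) for t in taxa]
        L = cholesky_factor(bm.matrix)
        eps = (L @ rng.standard_normal(bm.n))[order]
        depth = float(bm.matrix.diagonal().max())
        lin += cm.noise_scale * eps / np.sqrt(depth)

    H = rng.poisson(np.exp(lin) * pairs)

    rows = []
    flora_names = [f"flora{j + 1}" for j in range(cm.n_floras)]
    probs = np.full(cm.n_floras, 1.0 / cm.n_floras)
    for i, taxon in enumerate(taxa):
        sp = rng.multinomial(sizes[i], probs)
        if H[i] > 0 and sp.sum() > 0:
            hy = rng.multinomial(H[i], sp / sp.sum())
        else:
            hy = np.zeros(cm.n_floras, dtype=int)
        inter = (
            rng.poisson(cm.intergeneric_rate * sp / max(sp.sum(), 1))
            if cm.intergeneric_rate > 0
            else np.zeros(cm.n_floras, dtype=int)
        )
        for j in range(cm.n_floras):
            if sp[j] == 0 and hy[j] == 0 and inter[j] == 0:
                continue
            flagged = bool(
                cm.unspecified_fraction > 0
                and hy[j] > 0
                and rng.random() < cm.unspecified_fraction
            )
            rows.append(
                (taxon, f"fam_{taxon}", flora_names[j], int(sp[j]), int(hy[j]), int(inter[j]), flagged)
            )
    records = pd.DataFrame(rows, columns=FLORA_COLUMNS)
    truth = {
        "count_model": asdict(cm),
        "genus_sizes": {t: int(s) for t, s in zip(taxa, sizes)},
        "total_hybrids": {t: float(h) for t, h in zip(taxa, H)},
    }
    return records, truth


# ---------------------------------------------------------------------------
# Gaussian DAG data for path analysis


def simulate_path_dataset(
    tree: Phylogeny,
    coefficients: tuple[float, float] = (0.5, 0.3),
    seed=None,
    names: tuple[str, str, str] = ("woodiness", "perenniality", "hybridization"),
) -> pd.DataFrame:
    """Gaussian data generated under the causal chain W -> P -> H with BM
    errors: ``P = c1 W + e``, ``H = c2 P + e`` (unit-diagonal BM noise)."""
    c1, c2 = coefficients
    bm = bm_covariance(tree)
    depth = float(bm.matrix.diagonal().max())
    L = cholesky_factor(bm.matrix / depth)  # unit-variance BM deviates
    rng = _rng(seed)
    w = L @ rng.standard_normal(bm.n)
    p = c1 * w + L @ rng.standard_normal(bm.n)
    h = c2 * p + L @ rng.standard_normal(bm.n)
    df = pd.DataFrame({names[0]: w, names[1]: p, names[2]: h}, index=list(bm.taxa))
    df.index.name = "taxon"
    return df


# ---------------------------------------------------------------------------
# benchmark suite


#: Trait set mirroring the analysis traits (bounded scores plus genome size).
def _default_trait_specs(lam: float = 0.5) -> list[TraitSpec]:
    bounded = [
        "perenniality",
        "woodiness",
        "pollination_syndrome",
        "floral_symmetry",
        "outcrossing_rate",
        "breeding_system",
        "reproductive_system",
        "redlist",
        "agricultural",
    ]
    specs = [TraitSpec(name, lam=lam, sigma2=1.0, bounded=True) for name in bounded]
    specs.append(TraitSpec("c_value", lam=lam, sigma2=1.0, mean=0.5))
    specs.append(TraitSpec("cv_c_value", lam=0.0, sigma2=0.5, bounded=True))
    return specs


SCENARIOS = ("null", "perenniality-driven", "chain-causal", "family-structured")


@dataclass
class SyntheticDataset:
    """One fixture: tree + taxon trait table + flora records + ground truth."""

    name: str
    tree: Phylogeny
    traits: pd.DataFrame
    flora_records: pd.DataFrame
    truth: dict
    genus_to_family: dict | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tree.write(outdir / "tree.nwk")
        self.traits.to_csv(outdir / "traits.csv")
        self.flora_records.to_csv(outdir / "flora.csv", index=False)
        with open(outdir / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)
        if self.genus_to_family is not None:
            pd.Series(self.genus_to_family, name="family").rename_axis("genus").to_csv(
                outdir / "genus_to_family.csv"
            )


def _clade_families(tree: Phylogeny, depth_fraction: float = 0.35) -> dict[str, str]:
    """Group tips into 'families' = maximal clades older than a depth cutoff."""
    cutoff = depth_fraction * tree.depth
    fams: dict[str, str] = {}
    idx = 0
    for node in tree.tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._fam_depth
        node._fam_depth = parent_depth + (node.edge.length or 0.0)
        parent_done = node.parent_node is not None and getattr(node.parent_node, "_fam_id", None)
        if parent_done:
            node._fam_id = node.parent_node._fam_id
        elif node._fam_depth >= cutoff or node.is_leaf():
            idx += 1
            node._fam_id = f"F{idx}"
        else:
            node._fam_id = None
        if node.is_leaf():
            fams[node.taxon.label] = node._fam_id
    return fams


def make_benchmark_suite(
    scenarios=None,
    seed: int = 0,
    n_taxa: int = 300,
    n_floras: int = 8,
) -> dict[str, SyntheticDataset]:
    """Fixed-seed datasets for the four study scenarios.

    * ``null`` — no trait affects the hybrid rate;
    * ``perenniality-driven`` — a strong positive perenniality effect
      (log-rate slope 0.8 per trait SD);
    * ``chain-causal`` — woodiness drives perenniality (path 0.5) which
      drives the hybrid rate (path 0.3); no direct woodiness effect;
    * ``family-structured`` — a perenniality effect plus a genus-to-family
      map cut from the tree's deeper clades, for family-level aggregation.
    """
    if scenarios is None:
        scenarios = SCENARIOS
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValidationError(f"unknown scenario(s): {sorted(unknown)}; choose from {SCENARIOS}")

    out: dict[str, SyntheticDataset] = {}
    root = np.random.SeedSequence(seed)
    children = {name: s for name, s in zip(SCENARIOS, root.spawn(len(SCENARIOS)))}
    for name in scenarios:
        ss = children[name]
        tree_rng, trait_rng, count_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        tree = simulate_tree(n_taxa, birth_rate=1.0, seed=tree_rng, prefix="g")
        specs = _default_trait_specs()
        corr = np.eye(len(specs))
        if name == "chain-causal":
            # couple woodiness and perenniality deviates (W -> P path 0.5
            # corresponds to correlation 0.5/sqrt(1+0.25) of the deviates)
            i = [s.name for s in specs].index("woodiness")
            j = [s.name for s in specs].index("perenniality")
            rho = 0.5 / np.sqrt(1.25)
            corr[i, j] = corr[j, i] = rho
        traits, trait_truth = simulate_traits(tree, specs, correlation=corr, seed=trait_rng)
        effects = {}
        if name in ("perenniality-driven", "family-structured"):
            effects = {"perenniality": 0.8}
        elif name == "chain-causal":
            effects = {"perenniality": 0.3}
        cm = CountModel(effects=effects, n_floras=n_floras)
        records, count_truth = simulate_hybrid_counts(tree, traits, cm, seed=count_rng)
        g2f = _clade_families(tree) if name == "family-structured" else None
        if g2f is not None:
            records = records.assign(family=records["genus"].map(g2f))
        out[name] = SyntheticDataset(
            name=name,
            tree=tree,
            traits=traits,
            flora_records=records,
            truth={"scenario": name, "seed": seed, **trait_truth, **count_truth},
            genus_to_family=g2f,
        )
    return out
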