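"""End-to-end pipeline: counts -> metrics -> traits -> signal -> PGLS -> paths.

Stages are plain functions over a :class:`RunConfig`; each reads its inputs
(original files or earlier stage outputs in ``outdir``) and writes CSVs, so
running stages separately composes to the same result bundle as
:func:`run_full_pipeline`.  Every output CSV starts with a comment line
carrying the configuration hash and seed, and the log records the
per-analysis taxon count after pruning (sample sizes differ per trait
because missing data are pruned, never imputed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flora as fl
from . import traits as tr
from .errors import ValidationError
from .path import PathAnalysis, default_candidate_set
from .pgls import PGLS, benjamini_hochberg, compare_models, pearson_with_p
from .signal import PagelLambda
from .trees import Phylogeny, read_newick

logger = logging.getLogger("hybcorr")

__all__ = ["RunConfig", "load_config", "validate_inputs", "run_full_pipeline",
           "stage_metrics", "stage_traits", "stage_signal", "stage_pgls",
           "stage_correlations", "stage_path"]

METRICS = ("propensity", "ratio")
LOG_COLUMNS = {"propensity": "log_propensity", "ratio": "log_ratio"}


@dataclass
class RunConfig:
    """Paths, analysis switches and bookkeeping for one pipeline run."""

    flora_csv: str
    traits_csv: str
    genus_tree: str
    outdir: str
    family_tree: str | None = None
    genus_to_family_csv: str | None = None
    traits_format: str = "taxon"          # "taxon" (wide means) or "species" (long)
    levels: tuple = ("genus",)
    metrics: tuple = METRICS
    models: tuple = ("BM", "OU", "EB")
    fdr_q: float = 0.05
    log_offset_propensity: float = 1.0
    log_offset_ratio: float = 1.0
    min_taxa: int = 5
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.fdr_q < 1.0:
            raise ValidationError("fdr_q must be in (0, 1)")
        for lvl in self.levels:
            if lvl not in ("genus", "family"):
                raise ValidationError(f"unknown level {lvl!r}")
        if "family" in self.levels and self.family_tree is None:
            raise ValidationError("family-level analysis requires family_tree")

    def validate_paths(self) -> None:
        for attr in ("flora_csv", "traits_csv", "genus_tree", "family_tree",
                     "genus_to_family_csv"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{attr} does not exist: {path}")

    @property
    def config_hash(self) -> str:
        # identifies the analysis (inputs + switches), not the destination
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.md5(canonical.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("levels", "metrics", "models"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# hybcorr config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=index)


def _read_stage_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    problems: list = field(default_factory=list)
    prune_candidates: dict = field(default_factory=dict)
    trait_missingness: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_inputs(cfg: RunConfig, strict: bool = False) -> ValidationReport:
    """Cross-check taxon labels among counts, traits and trees; report
    per-trait missingness and taxa the exclusion rules would drop."""
    cfg.validate_paths()
    report = ValidationReport()
    try:
        records = fl.read_flora_csv(cfg.flora_csv)
    except ValidationError as exc:
        report.problems.append(str(exc))
        if strict:
            raise
        return report
    genera = set(records["genus"])
    tree = read_newick(cfg.genus_tree)
    tips = set(tree.tip_labels)
    report.prune_candidates["tree_tips_without_counts"] = sorted(tips - genera)
    report.prune_candidates["genera_missing_from_tree"] = sorted(genera - tips)

    traits = _load_trait_table(cfg, level="genus", restrict=None)
    miss = traits.isna().mean().rename("missing_fraction").to_frame()
    miss["n_observed"] = traits.notna().sum()
    report.trait_missingness = miss
    if strict and report.problems:
        raise ValidationError("; ".join(report.problems))
    return report


# ---------------------------------------------------------------------------
# stage: metrics


def stage_metrics(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    records = fl.read_flora_csv(cfg.flora_csv)
    tree = read_newick(cfg.genus_tree)
    genus = fl.aggregate_genus(records)
    unplaceable = sorted(set(genus["taxon"]) - set(tree.tip_labels))
    genus = fl.apply_exclusions(genus, records, drop_taxa=unplaceable)
    genus = fl.log_transform_metrics(
        genus, cfg.log_offset_propensity, cfg.log_offset_ratio
    )
    logger.info("metrics: %d genera after exclusions (%d unplaceable)",
                len(genus), len(unplaceable))
    out = {"genus": genus}
    _write_csv(genus, outdir / "metrics_genus.csv", cfg)
    if "family" in cfg.levels:
        mapping = None
        if cfg.genus_to_family_csv:
            m = pd.read_csv(cfg.genus_to_family_csv, comment="#")
            mapping = dict(zip(m["genus"], m["family"]))
        family = fl.aggregate_family(genus, mapping)
        ftree = read_newick(cfg.family_tree)
        family = family[family["taxon"].isin(ftree.tip_labels)].reset_index(drop=True)
        family = fl.log_transform_metrics(
            family, cfg.log_offset_propensity, cfg.log_offset_ratio
        )
        _write_csv(family, outdir / "metrics_family.csv", cfg)
        out["family"] = family
    return out


# ---------------------------------------------------------------------------
# stage: traits


def _load_trait_table(cfg: RunConfig, level: str, restrict=None) -> pd.DataFrame:
    if cfg.traits_format == "species":
        records = tr.read_trait_csv(cfg.traits_csv)
        profile = tr.taxon_trait_means(records, level=level)
        table = profile.means
    else:
        table = pd.read_csv(cfg.traits_csv, comment="#", index_col=0)
        table = table.drop(columns=[c for c in ("level",) if c in table.columns])
        if level == "family":
            table = _family_means_from_genus(cfg, table)
    if restrict is not None:
        table = table.loc[table.index.intersection(restrict)]
    return table


def _family_means_from_genus(cfg: RunConfig, genus_table: pd.DataFrame) -> pd.DataFrame:
    """Species-count-weighted family means of genus trait scores."""
    metrics_path = Path(cfg.outdir) / "metrics_genus.csv"
    if not metrics_path.exists():
        raise ValidationError("family trait means need metrics_genus.csv (run metrics first)")
    genus_metrics = _read_stage_csv(metrics_path).set_index("taxon")
    if cfg.genus_to_family_csv:
        m = pd.read_csv(cfg.genus_to_family_csv, comment="#")
        fam = pd.Series(dict(zip(m["genus"], m["family"])))
    else:
        fam = genus_metrics["family"]
    shared = genus_table.index.intersection(fam.index).intersection(genus_metrics.index)
    tab = genus_table.loc[shared]
    w = genus_metrics.loc[shared, "n"].astype(float)
    fam = fam.loc[shared]
    out = {}
    for trait in tab.columns:
        ok = tab[trait].notna() & (w > 0)
        grp = pd.DataFrame({"f": fam[ok], "x": tab.loc[ok, trait], "w": w[ok]})
        out[trait] = grp.groupby("f").apply(
            lambda g: np.average(g["x"], weights=g["w"]), include_groups=False
        )
    return pd.DataFrame(out)


def stage_traits(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    out = {}
    for level in cfg.levels:
        metrics = _read_stage_csv(outdir / f"metrics_{level}.csv")
        table = _load_trait_table(cfg, level, restrict=metrics["taxon"])
        table.index.name = "taxon"
        _write_csv(table, outdir / f"traits_{level}.csv", cfg, index=True)
        out[level] = table
    return out


# ---------------------------------------------------------------------------
# stage: phylogenetic signal


def _level_inputs(cfg: RunConfig, level: str):
    outdir = Path(cfg.outdir)
    metrics = _read_stage_csv(outdir / f"metrics_{level}.csv").set_index("taxon")
    traits = _read_stage_csv(outdir / f"traits_{level}.csv", index_col=0)
    tree = read_newick(cfg.genus_tree if level == "genus" else cfg.family_tree)
    return metrics, traits, tree


def stage_signal(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    out = {}
    for level in cfg.levels:
        metrics, traits, tree = _level_inputs(cfg, level)
        variables = {LOG_COLUMNS[m]: metrics[LOG_COLUMNS[m]] for m in cfg.metrics}
        variables.update({c: traits[c] for c in traits.columns})
        rows = []
        for name, series in variables.items():
            y = series.dropna()
            shared = y.index.intersection(tree.tip_labels)
            if len(shared) < 4:
                logger.warning("signal %s/%s: only %d taxa, skipped", level, name, len(shared))
                continue
            pruned = tree.prune_to(shared)
            res = PagelLambda(y.loc[shared], pruned).fit()
            logger.info("signal %s/%s: n=%d lambda=%.3f", level, name, res.nobs, res.lambda_)
            rows.append({"variable": name, **res.to_row()})
        table = pd.DataFrame(rows)
        _write_csv(table, outdir / f"signal_{level}.csv", cfg)
        out[level] = table
    return out


# ---------------------------------------------------------------------------
# stage: PGLS regressions


def stage_pgls(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    out = {}
    for level in cfg.levels:
        metrics, traits, tree = _level_inputs(cfg, level)
        rep_rows, model_rows = [], []
        for metric in cfg.metrics:
            ycol = LOG_COLUMNS[metric]
            for trait in traits.columns:
                data = pd.DataFrame({ycol: metrics[ycol], trait: traits[trait]}).dropna()
                shared = data.index.intersection(tree.tip_labels)
                if len(shared) < cfg.min_taxa:
                    logger.warning("pgls %s/%s~%s: only %d taxa, skipped",
                                   level, metric, trait, len(shared))
                    continue
                pruned = tree.prune_to(shared)
                data = data.loc[list(pruned.tip_labels)]
                fits = {}
                for model in cfg.models:
                    res = PGLS(data[ycol], data[trait], pruned, model=model).fit()
                    fits[model] = res
                    model_rows.append({"metric": metric, "trait": trait, **res.to_row()})
                if len(fits) >= 2:
                    comp = compare_models(fits)
                    rep = fits[comp.representative]
                else:
                    rep = next(iter(fits.values()))
                logger.info("pgls %s/%s~%s: n=%d representative=%s",
                            level, metric, trait, rep.nobs, rep.model)
                rep_rows.append({"metric": metric, "trait": trait, **rep.to_row()})
        rep = pd.DataFrame(rep_rows)
        if not rep.empty:
            flags = np.zeros(len(rep), dtype=bool)
            for metric in cfg.metrics:
                sel = rep["metric"] == metric
                if sel.any():
                    flags[sel.to_numpy()] = benjamini_hochberg(
                        rep.loc[sel, "p_value"].to_numpy(), q=cfg.fdr_q
                    )
            rep["bh_significant"] = flags
        _write_csv(rep, outdir / f"pgls_{level}.csv", cfg)
        _write_csv(pd.DataFrame(model_rows), outdir / f"pgls_models_{level}.csv", cfg)
        out[level] = rep
    return out


# ---------------------------------------------------------------------------
# stage: raw correlations


def stage_correlations(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    out = {}
    for level in cfg.levels:
        metrics, traits, _tree = _level_inputs(cfg, level)
        rows = []
        for metric in cfg.metrics:
            y = metrics[LOG_COLUMNS[metric]]
            for trait in traits.columns:
                pair = pd.DataFrame({"y": y, "x": traits[trait]}).dropna()
                if len(pair) < 3:
                    continue
                rc = pearson_with_p(pair["x"], pair["y"])
                rows.append({"metric": metric, "trait": trait, "r": rc.r,
                             "p_value": rc.p_value, "n": rc.n})
        table = pd.DataFrame(rows)
        _write_csv(table, outdir / f"correlations_{level}.csv", cfg)
        out[level] = table
    return out


# ---------------------------------------------------------------------------
# stage: path analysis


def stage_path(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    out = {}
    for level in cfg.levels:
        metrics, traits, tree = _level_inputs(cfg, level)
        for metric in cfg.metrics:
            ycol = LOG_COLUMNS[metric]
            need = ["woodiness", "perenniality"]
            if not all(c in traits.columns for c in need):
                logger.warning("path %s/%s: woodiness/perenniality unavailable", level, metric)
                continue
            data = pd.DataFrame(
                {
                    "woodiness": traits["woodiness"],
                    "perenniality": traits["perenniality"],
                    "hybridization": metrics[ycol],
                }
            ).dropna()
            shared = data.index.intersection(tree.tip_labels)
            if len(shared) < cfg.min_taxa:
                logger.warning("path %s/%s: only %d taxa, skipped", level, metric, len(shared))
                continue
            candidates = default_candidate_set()
            max_q = max(m.q() for m in candidates)
            if len(shared) <= max_q + 1:
                logger.warning("path %s/%s: n=%d too small for CICc (q up to %d), skipped",
                               level, metric, len(shared), max_q)
                continue
            analysis = PathAnalysis(data.loc[shared], tree.prune_to(shared), candidates)
            results = analysis.fit()
            logger.info("path %s/%s: n=%d best=%s", level, metric,
                        results.nobs, results.best.model.name)
            _write_csv(results.to_frame(), outdir / f"path_models_{level}_{metric}.csv", cfg)
            _write_csv(results.best.coefficients,
                       outdir / f"path_coefficients_{level}_{metric}.csv", cfg)
            out[f"{level}_{metric}"] = results.to_frame()
    return out


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the per-stage tables."""
    cfg.validate_paths()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    bundle = {
        "metrics": stage_metrics(cfg),
        "traits": stage_traits(cfg),
        "signal": stage_signal(cfg),
        "pgls": stage_pgls(cfg),
        "correlations": stage_correlations(cfg),
        "path": stage_path(cfg),
    }
    return bundle
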