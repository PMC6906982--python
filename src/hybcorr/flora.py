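"""Hybridization metrics from flora-derived counts.

Each record gives, for one genus in one regional flora, the number of
nonhybrid species and the number of distinct hybrid combinations observed
(a "hybrid" is a unique pair of parental species that has interbred, counted
once per flora).  Intergeneric hybrids are split half-and-half between the
two contributing genera, so hybrid counts may be half-integers.

Two metrics are computed per taxon after summing counts over floras:

* hybridization propensity = ``100 * H / (n (n - 1) / 2)`` — the realized
  percentage of possible within-group hybrid pairs.  Because ``H`` sums over
  floras while the pair denominator does not distinguish regions, genus-level
  values can exceed 100%.
* hybrid ratio = ``H / n`` — hybrid combinations per nonhybrid species.

Family metrics are means of the component-genus metrics weighted by genus
species counts; family ``n`` and ``H`` are sums.  Both metrics are
log-transformed (``ln(x + offset)``) before regression.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "FLORA_COLUMNS",
    "hybridization_propensity",
    "hybrid_ratio",
    "resolve_unspecified_hybrids",
    "read_flora_csv",
    "validate_flora_records",
    "aggregate_genus",
    "apply_exclusions",
    "aggregate_family",
    "log_transform_metrics",
]

FLORA_COLUMNS = [
    "genus",
    "family",
    "flora",
    "n_nonhybrid",
    "n_intrageneric_hybrids",
    "n_intergeneric_hybrid_halves",
    "unspecified_multiple",
]

SUMMARY_COLUMNS = ["taxon", "level", "n", "H", "propensity", "ratio"]


def hybridization_propensity(H, n):
    """Percent of possible hybrid pairs realized: ``100 H / (n(n-1)/2)``.

    Requires ``n >= 2``; groups with fewer nonhybrid species have no pair
    denominator and must be excluded by the caller.
    """
    H = np.asarray(H, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise UndefinedMetricError(
            "hybridization propensity undefined for n < 2 nonhybrid species"
        )
    if np.any(H < 0):
        raise ValidationError("hybrid count must be nonnegative")
    out = 100.0 * H / (n * (n - 1.0) / 2.0)
    return out if out.ndim else float(out)


def hybrid_ratio(H, n):
    """Hybrid combinations per nonhybrid species: ``H / n`` (``n >= 1``)."""
    H = np.asarray(H, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise UndefinedMetricError("hybrid ratio undefined for n = 0")
    if np.any(H < 0):
        raise ValidationError("hybrid count must be nonnegative")
    out = H / n
    return out if out.ndim else float(out)


def resolve_unspecified_hybrids(n):
    """Estimated hybrid count for a record flagged as producing "multiple
    hybrids" without further detail: the greater of 2 and 20% of the number
    of species present."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValidationError("species count must be >= 1 to resolve unspecified hybrids")
    out = np.maximum(2.0, 0.2 * n)
    return out if out.ndim else float(out)


def read_flora_csv(path) -> pd.DataFrame:
    """Read per-(genus, flora) count records; header row required, UTF-8."""
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in FLORA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"flora CSV missing columns: {missing}")
    df["unspecified_multiple"] = df["unspecified_multiple"].astype(bool)
    validate_flora_records(df)
    return df[FLORA_COLUMNS]


def validate_flora_records(records: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on structural problems."""
    problems = []
    for col in ("n_nonhybrid", "n_intrageneric_hybrids", "n_intergeneric_hybrid_halves"):
        if (records[col] < 0).any():
            problems.append(f"negative values in {col}")
    halves = records["n_intergeneric_hybrid_halves"].astype(float)
    if not np.allclose(halves * 2, np.round(halves * 2)):
        problems.append("intergeneric hybrid contributions must come in steps of 0.5")
    dupes = records.duplicated(subset=["genus", "flora"])
    if dupes.any():
        pairs = records.loc[dupes, ["genus", "flora"]].itertuples(index=False)
        problems.append("duplicate (genus, flora) records: " + ", ".join(map(str, pairs)))
    fam_counts = records.groupby("genus")["family"].nunique()
    multi = fam_counts[fam_counts > 1]
    if len(multi):
        problems.append(f"genera mapped to multiple families: {list(multi.index)}")
    if problems:
        raise ValidationError("; ".join(problems))


def _record_hybrid_count(records: pd.DataFrame, resolve_unspecified: bool = True) -> pd.Series:
    """Per-record hybrid contribution: intrageneric hybrids (resolved for
    unspecified-multiple flags) plus intergeneric halves at weight 0.5."""
    intra = records["n_intrageneric_hybrids"].astype(float).copy()
    if resolve_unspecified:
        flagged = records["unspecified_multiple"].astype(bool)
        if flagged.any():
            n_flag = records.loc[flagged, "n_nonhybrid"].astype(float)
            intra.loc[flagged] = resolve_unspecified_hybrids(np.maximum(n_flag, 1.0))
    return intra + 0.5 * records["n_intergeneric_hybrid_halves"].astype(float)


def aggregate_genus(records: pd.DataFrame, resolve_unspecified: bool = True) -> pd.DataFrame:
    """Sum counts over floras per genus and compute both metrics.

    ``n`` and ``H`` are plain sums across floras (no de-duplication of
    repeated species or hybrid pairs between regions).  Propensity is NaN
    where the summed ``n < 2``; ratio is NaN where ``n == 0``.
    """
    validate_flora_records(records)
    work = records.copy()
    work["_H"] = _record_hybrid_count(work, resolve_unspecified)
    grouped = work.groupby("genus", sort=True).agg(
        family=("family", "first"),
        n=("n_nonhybrid", "sum"),
        H=("_H", "sum"),
    )
    n = grouped["n"].to_numpy(dtype=float)
    H = grouped["H"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        propensity = np.where(n >= 2, 100.0 * H / np.where(n >= 2, n * (n - 1) / 2.0, np.nan), np.nan)
        ratio = np.where(n >= 1, H / np.where(n >= 1, n, np.nan), np.nan)
    out = pd.DataFrame(
        {
            "taxon": grouped.index,
            "level": "genus",
            "family": grouped["family"].to_numpy(),
            "n": n,
            "H": H,
            "propensity": propensity,
            "ratio": ratio,
        }
    ).reset_index(drop=True)
    return out


def apply_exclusions(
    summaries: pd.DataFrame,
    records: pd.DataFrame,
    drop_taxa=(),
) -> pd.DataFrame:
    """Remove genera with no chance of hybridization and unplaceable taxa.

    A genus is dropped when it was observed in exactly one flora, with a
    single nonhybrid species there, and contributed no hybrids.  ``drop_taxa``
    removes caller-specified taxa (e.g. missing from the phylogeny).
    """
    per_genus = records.groupby("genus")
    n_floras = per_genus["flora"].nunique()
    singletons = set()
    for genus, grp in per_genus:
        if (
            n_floras[genus] == 1
            and len(grp) == 1
            and grp["n_nonhybrid"].iloc[0] == 1
            and _record_hybrid_count(grp).iloc[0] == 0
        ):
            singletons.add(genus)
    keep = ~summaries["taxon"].isin(singletons | set(drop_taxa))
    return summaries.loc[keep].reset_index(drop=True)


def aggregate_family(
    genus_summaries: pd.DataFrame, genus_to_family: dict | None = None
) -> pd.DataFrame:
    """Family metrics as species-count-weighted means of genus metrics.

    ``n`` and ``H`` are sums over component genera.  Genera whose metric is
    undefined (NaN) are omitted from that metric's weighted mean.
    """
    work = genus_summaries.copy()
    if genus_to_family is not None:
        unmapped = sorted(set(work["taxon"]) - set(genus_to_family))
        if unmapped:
            raise ValidationError(f"genera without a family mapping: {unmapped}")
        work["family"] = work["taxon"].map(genus_to_family)
    elif "family" not in work.columns:
        raise ValidationError("provide genus_to_family or a 'family' column")

    rows = []
    for family, grp in work.groupby("family", sort=True):
        row = {"taxon": family, "level": "family", "n": grp["n"].sum(), "H": grp["H"].sum()}
        for metric in ("propensity", "ratio"):
            ok = grp[metric].notna() & (grp["n"] > 0)
            if ok.any():
                w = grp.loc[ok, "n"].to_numpy(dtype=float)
                row[metric] = float(np.average(grp.loc[ok, metric], weights=w))
            else:
                row[metric] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def log_transform_metrics(
    summaries: pd.DataFrame,
    offset_propensity: float = 1.0,
    offset_ratio: float = 1.0,
) -> pd.DataFrame:
    """Add ``log_propensity`` and ``log_ratio`` columns: ``ln(x + offset)``.

    An offset of zero is rejected whenever the corresponding metric contains
    zeros (log of zero).
    """
    out = summaries.copy()
    for metric, offset, col in (
        ("propensity", offset_propensity, "log_propensity"),
        ("ratio", offset_ratio, "log_ratio"),
    ):
        if offset < 0:
            raise ValueError("log offset must be nonnegative")
        x = out[metric].to_numpy(dtype=float)
        if offset == 0 and np.nanmin(x, initial=np.inf) <= 0:
            raise ValueError(f"{metric} contains zeros; a positive log offset is required")
        out[col] = np.log(x + offset)
    return out
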