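"""Species-level trait states to genus/family mean scores.

Categorical traits are coded on a 0 / 0.5 / 1 scale (0.5 for mixed or
combined states), the IUCN Red List category on a 0-5 scale, agricultural
status as a crop fraction, outcrossing rate as a proportion in [0, 1], and
genome size (C-value, picograms) as a mean-then-log summary together with a
coefficient of variation across per-ploidy-level means.  Taxon trait values
are unweighted means across all scored species in the taxon; missing traits
stay missing (never imputed or zero-filled).

Coding schemes
--------------
==================== ======================= ========================
trait                0                       1
==================== ======================= ========================
perenniality         annual                  perennial
woodiness            herbaceous              woody
pollination_syndrome abiotic                 biotic
floral_symmetry      actinomorphic           zygomorphic
breeding_system      asexual                 sexual
reproductive_system  vegetative              generative
agricultural         noncrop                 crop
==================== ======================= ========================

Intermediate / "both" states score 0.5.  Life-history compounds such as
``annual/biennial`` split unit mass equally over the listed categories;
the perenniality score is the perennial weight plus half the biennial
weight (so ``annual/biennial/perennial`` scores 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError, VocabularyError

__all__ = [
    "CATEGORICAL_TRAITS",
    "CONTINUOUS_TRAITS",
    "ALL_TRAITS",
    "score_categorical",
    "split_life_history",
    "perenniality_score",
    "score_redlist",
    "summarize_c_values",
    "score_species_table",
    "taxon_trait_means",
    "TraitProfiles",
    "read_trait_csv",
]

# state -> score vocabularies (extensible via a synonym map)
CATEGORICAL_TRAITS: dict[str, dict[str, float]] = {
    "woodiness": {"herbaceous": 0.0, "either": 0.5, "woody": 1.0},
    "pollination_syndrome": {"abiotic": 0.0, "both": 0.5, "biotic": 1.0},
    "floral_symmetry": {"actinomorphic": 0.0, "both": 0.5, "zygomorphic": 1.0},
    "breeding_system": {"asexual": 0.0, "both": 0.5, "sexual": 1.0},
    "reproductive_system": {"vegetative": 0.0, "both": 0.5, "generative": 1.0},
    "agricultural": {"noncrop": 0.0, "crop": 1.0},
}

REDLIST_SCORES: dict[str, float] = {
    "LC": 0.0,
    "NT": 0.5,
    "LR/nt": 0.5,
    "LR/cd": 1.0,
    "VU": 2.0,
    "EN": 3.0,
    "CR": 4.0,
    "EX": 5.0,
    "EW": 5.0,
}

#: Default raw-state synonyms; users can extend per run without code changes.
DEFAULT_SYNONYMS: dict[str, dict[str, str]] = {
    "pollination_syndrome": {"wind": "abiotic", "water": "abiotic", "insect": "biotic", "animal": "biotic"},
    "woodiness": {"herb": "herbaceous", "tree": "woody", "shrub": "woody", "liana": "woody"},
}

LIFE_HISTORY_CATEGORIES = ("annual", "biennial", "perennial")

CONTINUOUS_TRAITS = ("outcrossing_rate", "c_value")
ALL_TRAITS = (
    "perenniality",
    "woodiness",
    "pollination_syndrome",
    "floral_symmetry",
    "outcrossing_rate",
    "breeding_system",
    "reproductive_system",
    "c_value",
    "cv_c_value",
    "redlist",
    "agricultural",
)

TRAIT_CSV_COLUMNS = ["species", "genus", "family", "trait", "raw_state", "ploidy_level", "value"]


def _normalize(trait: str, state: str, synonyms=None) -> str:
    state = str(state).strip()
    merged = dict(DEFAULT_SYNONYMS.get(trait, {}))
    if synonyms:
        merged.update(synonyms.get(trait, {}))
    return merged.get(state.lower(), state)


def score_categorical(trait: str, raw_state: str, synonyms: dict | None = None) -> float:
    """Table-coded score for a categorical trait state (0, 0.5 or 1)."""
    if trait == "perenniality":
        return perenniality_score(raw_state)
    if trait == "redlist":
        return score_redlist(raw_state)
    if trait not in CATEGORICAL_TRAITS:
        raise VocabularyError(f"unknown categorical trait: {trait!r}")
    state = _normalize(trait, raw_state, synonyms)
    vocab = CATEGORICAL_TRAITS[trait]
    try:
        return vocab[state.lower()]
    except KeyError:
        raise VocabularyError(
            f"unknown state {raw_state!r} for trait {trait!r}; expected one of {sorted(vocab)}"
        ) from None


def split_life_history(raw_state: str) -> dict[str, float]:
    """Split unit mass equally among slash-joined life-history categories."""
    if raw_state is None or str(raw_state).strip() == "":
        raise VocabularyError("empty life-history state")
    parts = [p.strip().lower() for p in str(raw_state).split("/") if p.strip()]
    unknown = [p for p in parts if p not in LIFE_HISTORY_CATEGORIES]
    if unknown:
        raise VocabularyError(
            f"unknown life-history categories {unknown}; expected {LIFE_HISTORY_CATEGORIES}"
        )
    w = 1.0 / len(parts)
    weights = {c: 0.0 for c in LIFE_HISTORY_CATEGORIES}
    for p in parts:
        weights[p] += w
    return {c: v for c, v in weights.items() if v > 0}


def perenniality_score(raw_state: str) -> float:
    """Perennial weight plus half the biennial weight of the split state.

    Pure states map to 0 (annual) and 1 (perennial); the three-way compound
    ``annual/biennial/perennial`` scores 0.5.
    """
    w = split_life_history(raw_state)
    return w.get("perennial", 0.0) + 0.5 * w.get("biennial", 0.0)


def score_redlist(category: str) -> float:
    """IUCN Red List category to the 0-5 threat score."""
    cat = str(category).strip()
    try:
        return REDLIST_SCORES[cat]
    except KeyError:
        raise VocabularyError(
            f"unknown Red List category {category!r}; expected one of {sorted(REDLIST_SCORES)}"
        ) from None


def summarize_c_values(
    c_records: pd.DataFrame, ddof: int = 1
) -> tuple[pd.Series, float, float]:
    """Summarize genome sizes for one taxon.

    ``c_records`` needs columns ``species``, ``ploidy_level``, ``value``
    (picograms, > 0).  Returns ``(species_means, mean_log_c, cv)`` where

    * ``species_means`` averages all ploidy variants within each species,
    * ``mean_log_c`` is the log of the mean of species means (mean first,
      log last), and
    * ``cv`` is sd/mean across the per-(species, ploidy-level) mean
      C-values of the taxon (sample sd by default, ``ddof=0`` for
      population sd).
    """
    vals = c_records["value"].astype(float)
    if (vals <= 0).any():
        raise ValidationError("C-values must be positive (picograms)")
    ploidy = c_records["ploidy_level"].fillna(1)
    per_ploidy = c_records.assign(_v=vals).groupby(
        ["species", ploidy.rename("ploidy_level")]
    )["_v"].mean()
    species_means = per_ploidy.groupby("species").mean()
    mean_log_c = float(np.log(species_means.mean()))
    m = per_ploidy.to_numpy()
    if len(m) < 2:
        cv = 0.0
    else:
        cv = float(np.std(m, ddof=ddof) / np.mean(m))
    return species_means, mean_log_c, cv


def read_trait_csv(path) -> pd.DataFrame:
    """Long-format species trait table (one row per species x trait record)."""
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    required = ["species", "genus", "family", "trait", "raw_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trait CSV missing columns: {missing}")
    for opt in ("ploidy_level", "value"):
        if opt not in df.columns:
            df[opt] = np.nan
    return df[TRAIT_CSV_COLUMNS]


def score_species_table(records: pd.DataFrame, synonyms: dict | None = None) -> pd.DataFrame:
    """Attach a numeric ``score`` to every categorical/continuous record.

    C-value records pass through unscored (they are summarized separately by
    :func:`summarize_c_values` inside :func:`taxon_trait_means`).
    """
    rows = []
    for rec in records.itertuples(index=False):
        if rec.trait == "c_value":
            continue
        if rec.trait == "outcrossing_rate":
            val = float(rec.value)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"outcrossing rate {val} outside [0, 1] for {rec.species}")
            score = val
        else:
            score = score_categorical(rec.trait, rec.raw_state, synonyms)
        rows.append((rec.species, rec.genus, rec.family, rec.trait, score))
    return pd.DataFrame(rows, columns=["species", "genus", "family", "trait", "score"])


@dataclass
class TraitProfiles:
    """Per-taxon trait means with the species counts behind each mean."""

    level: str
    means: pd.DataFrame   # index = taxon, columns = traits
    counts: pd.DataFrame  # same shape; n_species_scored per trait

    def to_csv(self, path) -> None:
        out = self.means.copy()
        out.insert(0, "level", self.level)
        out.to_csv(path, index_label="taxon")


def taxon_trait_means(
    records: pd.DataFrame,
    level: str = "genus",
    synonyms: dict | None = None,
    cv_ddof: int = 1,
) -> TraitProfiles:
    """Unweighted species-mean trait profile per genus or family.

    Family means pool species directly (equivalent to genus means weighted
    by species count).  Traits with no scored species in a taxon are left
    missing.  Genome size contributes two columns: ``c_value`` (log of the
    mean of species-mean C-values, log picograms) and ``cv_c_value``.
    """
    if level not in ("genus", "family"):
        raise ValueError("level must be 'genus' or 'family'")
    scored = score_species_table(records, synonyms)
    if scored.empty and records.empty:
        raise ValidationError("no trait records supplied")
    means = (
        scored.groupby([level, "trait"])["score"].mean().unstack("trait")
        if not scored.empty
        else pd.DataFrame()
    )
    counts = (
        scored.groupby([level, "trait"])["score"].count().unstack("trait")
        if not scored.empty
        else pd.DataFrame()
    )

    cvals = records[records["trait"] == "c_value"]
    if not cvals.empty:
        logc, cv, nsp = {}, {}, {}
        for taxon, grp in cvals.groupby(level):
            species_means, mean_log_c, cv_val = summarize_c_values(grp, ddof=cv_ddof)
            logc[taxon] = mean_log_c
            cv[taxon] = cv_val
            nsp[taxon] = len(species_means)
        means = means.join(pd.Series(logc, name="c_value"), how="outer")
        means = means.join(pd.Series(cv, name="cv_c_value"), how="outer")
        counts = counts.join(pd.Series(nsp, name="c_value"), how="outer")
        counts = counts.join(pd.Series(nsp, name="cv_c_value"), how="outer")

    means.index.name = "taxon"
    counts = counts.reindex(index=means.index, columns=means.columns).fillna(0).astype(int)
    return TraitProfiles(level=level, means=means.sort_index(), counts=counts.sort_index())
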