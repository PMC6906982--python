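"""Trait coding schemes, life-history splitting and genome-size summaries."""

import numpy as np
import pandas as pd
import pytest

from hybcorr.errors import ValidationError, VocabularyError
from hybcorr.traits import (
    perenniality_score,
    score_categorical,
    score_redlist,
    split_life_history,
    summarize_c_values,
    taxon_trait_means,
)


@pytest.mark.parametrize(
    "trait, state, expected",
    [
        ("pollination_syndrome", "abiotic", 0.0),
        ("pollination_syndrome", "both", 0.5),
        ("pollination_syndrome", "biotic", 1.0),
        ("pollination_syndrome", "wind", 0.0),      # synonym
        ("woodiness", "either", 0.5),
        ("woodiness", "shrub", 1.0),                # synonym
        ("reproductive_system", "generative", 1.0),
        ("breeding_system", "asexual", 0.0),
        ("floral_symmetry", "zygomorphic", 1.0),
        ("agricultural", "crop", 1.0),
    ],
)
def test_categorical_codes(trait, state, expected):
    assert score_categorical(trait, state) == expected


def test_unknown_state_names_trait_and_state():
    with pytest.raises(VocabularyError, match="woodiness"):
        score_categorical("woodiness", "spongy")


def test_custom_synonyms():
    syn = {"woodiness": {"arborescent": "woody"}}
    assert score_categorical("woodiness", "arborescent", synonyms=syn) == 1.0


def test_split_life_history():
    assert split_life_history("annual/biennial") == {"annual": 0.5, "biennial": 0.5}
    assert split_life_history("perennial") == {"perennial": 1.0}
    with pytest.raises(VocabularyError):
        split_life_history("")


@pytest.mark.parametrize(
    "state, expected",
    [
        ("annual", 0.0),
        ("perennial", 1.0),
        ("annual/biennial/perennial", 0.5),
        ("annual/perennial", 0.5),
        ("annual/biennial", 0.25),
    ],
)
def test_perenniality_score(state, expected):
    assert perenniality_score(state) == pytest.approx(expected)


def test_life_history_weights_sum_to_one():
    for state in ("annual", "annual/biennial", "biennial/perennial",
                  "annual/biennial/perennial"):
        assert sum(split_life_history(state).values()) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "cat, expected",
    [("LC", 0.0), ("NT", 0.5), ("LR/nt", 0.5), ("LR/cd", 1.0), ("VU", 2.0),
     ("EN", 3.0), ("CR", 4.0), ("EX", 5.0), ("EW", 5.0)],
)
def test_redlist_scores(cat, expected):
    assert score_redlist(cat) == expected


def test_redlist_unknown():
    with pytest.raises(VocabularyError):
        score_redlist("XX")


def _c_records(values, species="sp1", ploidies=None):
    n = len(values)
    return pd.DataFrame(
        {
            "species": [species] * n if isinstance(species, str) else species,
            "ploidy_level": ploidies if ploidies is not None else [1] * n,
            "value": values,
        }
    )


def test_c_value_single_record_cv_zero():
    _, logc, cv = summarize_c_values(_c_records([2.0]))
    assert cv == 0.0
    assert logc == pytest.approx(np.log(2.0))


def test_c_value_cv_across_ploidy_means():
    # two ploidy-level means {1, 3}: sample sd sqrt(2), mean 2
    _, _, cv = summarize_c_values(_c_records([1.0, 3.0], ploidies=[2, 4]))
    assert cv == pytest.approx(np.sqrt(2.0) / 2.0)
    _, _, cv_pop = summarize_c_values(_c_records([1.0, 3.0], ploidies=[2, 4]), ddof=0)
    assert cv_pop == pytest.approx(0.5)


def test_c_value_mean_then_log():
    recs = _c_records([1.0, 4.0], species=["a", "b"], ploidies=[1, 1])
    _, logc, _ = summarize_c_values(recs)
    assert logc == pytest.approx(np.log(2.5))


def test_c_value_rejects_nonpositive():
    with pytest.raises(ValidationError):
        summarize_c_values(_c_records([0.0]))


def test_cv_scale_invariance_and_log_shift(rng):
    vals = rng.uniform(0.5, 8.0, 6)
    recs = _c_records(list(vals), species=list("abcdef"), ploidies=[1] * 6)
    _, logc, cv = summarize_c_values(recs)
    scaled = recs.assign(value=recs["value"] * 3.0)
    _, logc3, cv3 = summarize_c_values(scaled)
    assert cv3 == pytest.approx(cv)
    assert logc3 == pytest.approx(logc + np.log(3.0))


def _species_table():
    rows = [
        # species, genus, family, trait, raw_state, ploidy, value
        ("s1", "G1", "F1", "woodiness", "herbaceous", None, None),
        ("s2", "G1", "F1", "woodiness", "either", None, None),
        ("s3", "G1", "F1", "woodiness", "woody", None, None),
        ("s1", "G1", "F1", "perenniality", "annual", None, None),
        ("s2", "G1", "F1", "perenniality", "perennial", None, None),
        ("s1", "G1", "F1", "agricultural", "crop", None, None),
        ("s2", "G1", "F1", "agricultural", "noncrop", None, None),
        ("s3", "G1", "F1", "agricultural", "noncrop", None, None),
        ("s4", "G1", "F1", "agricultural", "noncrop", None, None),
        ("s5", "G2", "F1", "outcrossing_rate", None, None, 0.7),
        ("s1", "G1", "F1", "c_value", None, 1, 1.0),
        ("s2", "G1", "F1", "c_value", None, 1, 4.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "genus", "family", "trait", "raw_state", "ploidy_level", "value"],
    )


def test_taxon_means_genus_level():
    prof = taxon_trait_means(_species_table(), level="genus")
    g1 = prof.means.loc["G1"]
    assert g1["woodiness"] == pytest.approx(0.5)
    assert g1["perenniality"] == pytest.approx(0.5)
    assert g1["agricultural"] == pytest.approx(0.25)
    assert g1["c_value"] == pytest.approx(np.log(2.5))
    assert np.isnan(g1.get("outcrossing_rate", np.nan)) or "outcrossing_rate" not in g1
    assert prof.counts.loc["G1", "woodiness"] == 3


def test_missing_trait_stays_missing_not_zero():
    prof = taxon_trait_means(_species_table(), level="genus")
    # G2 has only outcrossing data; every categorical mean must be missing
    g2 = prof.means.loc["G2"]
    assert np.isnan(g2["woodiness"])
    assert g2["outcrossing_rate"] == pytest.approx(0.7)


def test_family_pooling_equals_species_mean():
    prof = taxon_trait_means(_species_table(), level="family")
    assert prof.means.loc["F1", "woodiness"] == pytest.approx(0.5)


def test_mean_fixed_point():
    """Adding a species at the current mean leaves the mean unchanged."""
    base = _species_table()
    prof = taxon_trait_means(base, level="genus")
    mean_w = prof.means.loc["G1", "woodiness"]
    extra = pd.DataFrame(
        [["s9", "G1", "F1", "woodiness", "either", np.nan, np.nan]], columns=base.columns
    )
    prof2 = taxon_trait_means(
        pd.concat([base.astype(extra.dtypes), extra], ignore_index=True), level="genus"
    )
    assert prof2.means.loc["G1", "woodiness"] == pytest.approx(mean_w)


def test_outcrossing_bounds_enforced():
    bad = _species_table()
    bad.loc[bad["trait"] == "outcrossing_rate", "value"] = 1.4
    with pytest.raises(ValidationError):
        taxon_trait_means(bad, level="genus")
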