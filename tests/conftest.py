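import numpy as np
import pandas as pd
import pytest

from hybcorr import Phylogeny, simulate_tree


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — the worked example used across tree tests."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def medium_tree() -> Phylogeny:
    return simulate_tree(60, birth_rate=1.0, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def flora_records() -> pd.DataFrame:
    """Five genera across two floras, exercising every counting rule:

    - Carex appears in both floras (counts sum);
    - Salix has one intergeneric hybrid half (weight 0.5);
    - Erigeron is a single-species, single-flora genus with no hybrids
      (excluded downstream);
    - Rosa is flagged unspecified-multiple (resolved to max(2, 0.2 n));
    - Viola is a single-flora genus with 2 species (retained).
    """
    cols = [
        "genus", "family", "flora", "n_nonhybrid", "n_intrageneric_hybrids",
        "n_intergeneric_hybrid_halves", "unspecified_multiple",
    ]
    rows = [
        ("Carex", "Cyperaceae", "west", 3, 1, 0, False),
        ("Carex", "Cyperaceae", "east", 3, 1, 0, False),
        ("Salix", "Salicaceae", "west", 4, 0, 1, False),
        ("Erigeron", "Asteraceae", "east", 1, 0, 0, False),
        ("Rosa", "Rosaceae", "west", 30, 1, 0, True),
        ("Viola", "Violaceae", "east", 2, 0, 0, False),
    ]
    return pd.DataFrame(rows, columns=cols)
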