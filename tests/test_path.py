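"""d-separation basis sets, Fisher's C, CICc, and path-coefficient fits."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hybcorr import (
    PathAnalysis,
    PathModel,
    basis_set,
    cicc,
    default_candidate_set,
    fishers_c,
    simulate_path_dataset,
    simulate_tree,
)
from hybcorr.errors import ValidationError
from hybcorr.gls import cholesky_factor, gls_fit
from hybcorr.trees import bm_covariance


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cyclic"):
            PathModel("bad", (("a", "b"), ("b", "a")))

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError):
            PathModel("bad", (("a", "a"),))

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValidationError):
            PathModel("bad", (("a", "b"), ("a", "b")))

    def test_default_candidates(self):
        models = default_candidate_set()
        assert len(models) == 5
        assert models[0].n_edges == 2          # the chain W -> P -> H
        for m in models:
            assert nx.is_directed_acyclic_graph(m.graph())
        # the saturated variants have no testable claims
        for m in models[2:]:
            assert basis_set(m) == []


class TestBasisSet:
    def test_chain(self):
        claims = basis_set(PathModel("chain", (("W", "P"), ("P", "H"))))
        assert len(claims) == 1
        c = claims[0]
        assert (c.x, c.y, c.given) == ("W", "H", ("P",))

    def test_common_cause(self):
        claims = basis_set(PathModel("fork", (("W", "P"), ("W", "H"))))
        assert len(claims) == 1
        c = claims[0]
        assert {c.x, c.y} == {"P", "H"} and c.given == ("W",)

    def test_complete_dag_empty(self):
        m = PathModel("full", (("a", "b"), ("a", "c"), ("b", "c")))
        assert basis_set(m) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_claims_hold_by_graphical_d_separation(self, seed):
        """Every emitted claim is a true d-separation statement of the DAG
        (graph-theoretic oracle), and claims cover exactly the non-adjacent
        pairs."""
        rng = np.random.default_rng(seed)
        nodes = list("abcde")
        edges = tuple(
            (nodes[i], nodes[j])
            for i, j in itertools.combinations(range(5), 2)
            if rng.random() < 0.4
        )
        model = PathModel(f"r{seed}", edges, nodes=tuple(nodes))
        claims = basis_set(model)
        g = model.graph()
        nonadjacent = {
            frozenset((a, b))
            for a, b in itertools.combinations(nodes, 2)
            if not g.has_edge(a, b) and not g.has_edge(b, a)
        }
        assert {frozenset((c.x, c.y)) for c in claims} == nonadjacent
        for c in claims:
            assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.given))


class TestFishersC:
    def test_arithmetic(self):
        C, df, p = fishers_c([0.5, 0.5])
        assert C == pytest.approx(-2 * (np.log(0.5) + np.log(0.5)))
        assert C == pytest.approx(2.7726, abs=1e-4)
        assert df == 4

    def test_empty_is_saturated(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_p_one_contributes_nothing(self):
        C, df, p = fishers_c([1.0])
        assert C == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_zero_p_floored(self):
        C, df, p = fishers_c([0.0])
        assert np.isfinite(C) and C > 0


class TestCICc:
    def test_worked_example(self):
        assert cicc(2.7726, 3, 20) == pytest.approx(2.7726 + 6 * 20 / 16)

    def test_no_parameters(self):
        assert cicc(5.0, 0, 30) == 5.0

    def test_aic_limit(self):
        assert cicc(1.0, 4, 10**7) == pytest.approx(1.0 + 8.0, abs=1e-4)

    def test_undefined(self):
        with pytest.raises(ValueError):
            cicc(1.0, 10, 11)


@pytest.fixture(scope="module")
def chain_setup():
    tree = simulate_tree(150, seed=21)
    data = simulate_path_dataset(tree, (0.8, 0.6), seed=22)
    return tree, data


class TestPathAnalysis:
    def test_perfect_dependence_claim(self, chain_setup):
        tree, data = chain_setup
        frame = data.copy()
        frame["H"] = frame["woodiness"]
        pa = PathAnalysis(frame, tree, [PathModel("m", (("perenniality", "H"),),
                                                  nodes=("woodiness", "perenniality", "H"))])
        claims = basis_set(pa.models[0])
        [claim] = [c for c in claims if {c.x, c.y} == {"woodiness", "H"}]
        assert pa.test_claim(claim) < 1e-10

    def test_chain_recovery_single_dataset(self, chain_setup):
        tree, data = chain_setup
        results = PathAnalysis(data, tree).fit()
        # the reverse chain must be strongly rejected with these effects
        by_name = {f.model.name: f for f in results.fits}
        assert by_name["m2_chain_pwh"].p_value < 0.01
        assert results.best.model.name in (
            "m1_chain_wph", "m3_wph_plus_wh", "m4_pwh_plus_ph", "m5_both_direct"
        )

    def test_ranking_invariant_to_model_order(self, chain_setup):
        tree, data = chain_setup
        models = default_candidate_set()
        a = PathAnalysis(data, tree, models).fit().to_frame()["model"]
        b = PathAnalysis(data, tree, models[::-1]).fit().to_frame()["model"]
        pd.testing.assert_series_equal(a, b)

    def test_identical_models_tie_break_by_name(self, chain_setup):
        tree, data = chain_setup
        m1 = PathModel("a_copy", (("woodiness", "perenniality"), ("perenniality", "hybridization")))
        m2 = PathModel("b_copy", m1.edges)
        fits = PathAnalysis(data, tree, [m2, m1]).fit().fits
        assert fits[0].cicc == pytest.approx(fits[1].cicc)
        assert fits[0].model.name == "a_copy"

    def test_coefficients_match_multiparent_gls(self, chain_setup):
        """An edge into a two-parent node equals the slope of a two-predictor
        GLS on the standardized data."""
        tree, data = chain_setup
        model = PathModel("sat", (("woodiness", "hybridization"),
                                  ("perenniality", "hybridization"),
                                  ("woodiness", "perenniality")))
        pa = PathAnalysis(data, tree, [model])
        fit = pa.fit_model(model)
        coefs = fit.coefficients.set_index(["source", "target"])
        z = pa.data
        C = bm_covariance(pa.phylogeny).subset(list(z.index)).matrix
        X = np.column_stack([
            np.ones(len(z)), z["perenniality"].to_numpy(), z["woodiness"].to_numpy()
        ])
        direct = gls_fit(z["hybridization"].to_numpy(), X, C)
        assert coefs.loc[("perenniality", "hybridization"), "estimate"] == pytest.approx(
            direct.params[1], abs=1e-10
        )
        assert coefs.loc[("woodiness", "hybridization"), "estimate"] == pytest.approx(
            direct.params[2], abs=1e-10
        )

    def test_standardized_perfect_edge_is_one(self):
        tree = simulate_tree(40, seed=30)
        rng = np.random.default_rng(31)
        x = pd.Series(rng.normal(size=40), index=list(tree.tip_labels))
        frame = pd.DataFrame({"x": x, "y": 2.0 * x})
        pa = PathAnalysis(frame, tree, [PathModel("e", (("x", "y"),))])
        fit = pa.fit_model(pa.models[0])
        assert fit.coefficients["estimate"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_coefficient_recovery(self):
        """Standardized path coefficients approach the generating values."""
        estimates = []
        tree = simulate_tree(200, seed=41)
        for rep in range(10):
            data = simulate_path_dataset(tree, (0.5, 0.3), seed=500 + rep)
            pa = PathAnalysis(data, tree, [PathModel(
                "chain", (("woodiness", "perenniality"), ("perenniality", "hybridization"))
            )])
            fit = pa.fit_model(pa.models[0])
            coefs = fit.coefficients.set_index(["source", "target"])["estimate"]
            estimates.append([
                coefs[("woodiness", "perenniality")],
                coefs[("perenniality", "hybridization")],
            ])
        mean = np.mean(estimates, axis=0)
        # standardized truth = corr of the generating linear model:
        # var(P) = 1.25, var(H) = 0.09 * 1.25 + 1 = 1.1125
        assert mean[0] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.1)
        assert mean[1] == pytest.approx(0.3 * np.sqrt(1.25 / 1.1125), abs=0.1)
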