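"""Newick handling, pruning, and BM/lambda/OU/EB covariance construction."""

import numpy as np
import pytest

from hybcorr import (
    Phylogeny,
    bm_covariance,
    eb_transform,
    lambda_transform,
    ou_transform,
    simulate_tree,
)
from hybcorr.errors import ModelAssumptionError, TreeError
from hybcorr.gls import cholesky_factor


class TestNewickIO:
    def test_parse_three_tips(self, three_tip_tree):
        assert set(three_tip_tree.tip_labels) == {"A", "B", "C"}
        assert three_tip_tree.depths() == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_missing_semicolon_rejected(self):
        with pytest.raises(TreeError, match="malformed"):
            Phylogeny.from_newick("((A:1,B:1):1,C:2)")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_missing_length_rejected(self):
        with pytest.raises(TreeError, match="branch length"):
            Phylogeny.from_newick("((A:1,B):1,C:2);")

    def test_round_trip(self, tmp_path, medium_tree):
        path = tmp_path / "t.nwk"
        medium_tree.write(path)
        back = Phylogeny.read(path)
        assert set(back.tip_labels) == set(medium_tree.tip_labels)
        d0, d1 = medium_tree.depths(), back.depths()
        for tip in d0:
            assert d1[tip] == pytest.approx(d0[tip], rel=1e-9)


class TestPruning:
    def test_identity(self, three_tip_tree):
        pruned = three_tip_tree.prune_to({"A", "B", "C"})
        assert pruned.depths() == three_tip_tree.depths()

    def test_depths_preserved(self, three_tip_tree):
        pruned = three_tip_tree.prune_to({"A", "B"})
        assert set(pruned.tip_labels) == {"A", "B"}
        assert pruned.depths() == {"A": 2.0, "B": 2.0}

    def test_below_minimum(self, three_tip_tree):
        with pytest.raises(TreeError):
            three_tip_tree.prune_to({"A"})

    def test_unknown_taxon(self, three_tip_tree):
        with pytest.raises(TreeError, match="not in tree"):
            three_tip_tree.prune_to({"A", "Z"})

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_prune_commutes_with_bm_covariance(self, seed):
        """Covariance of the pruned tree == submatrix of the full covariance."""
        tree = simulate_tree(25, seed=seed)
        rng = np.random.default_rng(seed + 100)
        keep = list(rng.choice(tree.tip_labels, size=12, replace=False))
        full = bm_covariance(tree).subset(keep)
        pruned = bm_covariance(tree.prune_to(keep)).subset(keep)
        np.testing.assert_allclose(pruned.matrix, full.matrix, atol=1e-10)


class TestBMCovariance:
    def test_shared_path_lengths(self, three_tip_tree):
        cov = bm_covariance(three_tip_tree).subset(["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(cov.matrix, expected)

    def test_star_tree_diagonal(self, star_tree):
        C = bm_covariance(star_tree).matrix
        np.testing.assert_allclose(C, np.eye(4))

    def test_ultrametric_constant_diagonal(self, medium_tree):
        C = bm_covariance(medium_tree).matrix
        np.testing.assert_allclose(np.diag(C), np.diag(C)[0], rtol=1e-9)

    def test_polytomy_supported(self):
        C = bm_covariance(Phylogeny.from_newick("((A:1,B:1,C:1):1,D:2);")).subset(
            ["A", "B", "C", "D"]
        ).matrix
        assert C[0, 1] == C[0, 2] == C[1, 2] == 1.0
        assert C[0, 3] == 0.0

    def test_zero_terminal_branch_warns_and_jitters(self):
        tree = Phylogeny.from_newick("((A:0,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="zero-length"):
            C = bm_covariance(tree).matrix
        cholesky_factor(C)  # must be factorizable after the jitter

    @pytest.mark.parametrize("seed", [11, 12])
    def test_cholesky_after_jitter(self, seed):
        tree = simulate_tree(40, seed=seed)
        C = bm_covariance(tree).matrix
        L = cholesky_factor(C + 1e-10 * np.trace(C) * np.eye(len(C)))
        assert np.all(np.isfinite(L))


class TestTransforms:
    def test_lambda_identity_and_star(self, medium_tree):
        bm = bm_covariance(medium_tree)
        np.testing.assert_allclose(lambda_transform(bm, 1.0).matrix, bm.matrix)
        lam0 = lambda_transform(bm, 0.0).matrix
        np.testing.assert_allclose(lam0, np.diag(np.diag(bm.matrix)))

    def test_lambda_scales_offdiagonal(self, three_tip_tree):
        bm = bm_covariance(three_tip_tree)
        half = lambda_transform(bm, 0.5).subset(["A", "B"]).matrix
        assert half[0, 1] == pytest.approx(0.5)
        assert half[0, 0] == pytest.approx(2.0)

    def test_lambda_domain(self, three_tip_tree):
        with pytest.raises(ValueError):
            lambda_transform(bm_covariance(three_tip_tree), 1.2)

    def test_ou_point_value(self):
        # depth T=2, shared time 1, alpha=0.5 -> e^-1 (1 - e^-1)
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C = ou_transform(tree, 0.5).subset(["A", "B"]).matrix
        assert C[0, 1] == pytest.approx(np.exp(-1) * (1 - np.exp(-1)), rel=1e-12)

    def test_ou_limits(self, medium_tree, three_tip_tree):
        bm = bm_covariance(medium_tree)
        near = ou_transform(medium_tree, 1e-8, bm=bm).matrix
        assert np.max(np.abs(near - bm.matrix)) < 1e-6
        # strong pull wipes out covariance between taxa that split well
        # before the present (t_ij < T)
        far = ou_transform(three_tip_tree, 50.0).matrix
        off = far - np.diag(np.diag(far))
        assert np.max(np.abs(off)) < 1e-12

    def test_ou_requires_ultrametric(self):
        tree = Phylogeny.from_newick("((A:1,B:2):1,C:4);")
        with pytest.raises(ModelAssumptionError):
            ou_transform(tree, 0.5)

    def test_eb_point_value(self, three_tip_tree):
        C = eb_transform(three_tip_tree, -1.0).subset(["A", "B"]).matrix
        assert C[0, 1] == pytest.approx((np.exp(-1) - 1) / (-1), rel=1e-12)

    def test_eb_limits(self, medium_tree):
        bm = bm_covariance(medium_tree)
        near = eb_transform(medium_tree, -1e-8, bm=bm).matrix
        assert np.max(np.abs(near - bm.matrix)) < 1e-6
        deep = eb_transform(medium_tree, -100.0, bm=bm).matrix
        assert np.max(deep) <= 1 / 100.0 + 1e-12

    def test_eb_domain(self, medium_tree):
        with pytest.raises(ValueError):
            eb_transform(medium_tree, 0.5)

    @pytest.mark.parametrize("model", ["bm", "lam", "ou", "eb"])
    def test_transforms_symmetric_and_factorizable(self, medium_tree, model):
        bm = bm_covariance(medium_tree)
        C = {
            "bm": bm.matrix,
            "lam": lambda_transform(bm, 0.37).matrix,
            "ou": ou_transform(medium_tree, 1.3, bm=bm).matrix,
            "eb": eb_transform(medium_tree, -0.8, bm=bm).matrix,
        }[model]
        np.testing.assert_allclose(C, C.T, atol=1e-10)
        cholesky_factor(C + 1e-10 * np.trace(C) * np.eye(len(C)))
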