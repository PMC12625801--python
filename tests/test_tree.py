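"""Tree parsing, manipulation, and phylogenetic covariance construction."""

import numpy as np
import pytest
from oracles import tip_depths_dendropy

from phylomass import (
    NewickParseError,
    lambda_transform,
    parse_newick,
    prune_to_taxa,
    resolve_polytomies,
    simulate_tree,
    vcv_from_tree,
)


class TestParseNewick:
    def test_two_tip_tree(self):
        tree = parse_newick("(A:1,B:1):0;")
        assert sorted(tree.tip_labels) == ["A", "B"]
        assert tree.depths() == {"A": 1.0, "B": 1.0}

    @pytest.mark.parametrize(
        "bad", ["(A:1,(B:1):0.5", "(A:1,A:1):0;", "((A:1,B:1:0;"]
    )
    def test_malformed_or_duplicate_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_roundtrip_preserves_covariance(self, extant_tree):
        again = parse_newick(extant_tree.write_newick())
        c1 = vcv_from_tree(extant_tree, sorted(extant_tree.tip_labels)).C
        c2 = vcv_from_tree(again, sorted(extant_tree.tip_labels)).C
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_reference_tree_has_62_unique_tips(self, extant_tree):
        labels = extant_tree.tip_labels
        assert len(labels) == 62
        assert len(set(labels)) == 62

    def test_underscore_and_space_labels_match(self):
        tree = parse_newick("(Homo_sapiens:1,'Pan troglodytes':1):0;")
        assert set(tree.tip_labels) == {"Homo sapiens", "Pan troglodytes"}


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, three_taxon_tree):
        out = resolve_polytomies(three_taxon_tree, seed=0)
        c0 = vcv_from_tree(three_taxon_tree, ["A", "B", "C"]).C
        c1 = vcv_from_tree(out, ["A", "B", "C"]).C
        np.testing.assert_allclose(c0, c1, atol=1e-12)
        assert out.is_binary()

    def test_trifurcation_covariance_invariant(self):
        tri = parse_newick("(A:1,B:1,C:1):0;")
        out = resolve_polytomies(tri, seed=3)
        assert out.is_binary()
        taxa = ["A", "B", "C"]
        np.testing.assert_allclose(
            vcv_from_tree(tri, taxa).C, vcv_from_tree(out, taxa).C, atol=1e-12
        )

    def test_five_way_polytomy_seed_invariant_covariance(self):
        poly = parse_newick("(A:2,B:2,C:2,D:2,E:2):0;")
        taxa = list("ABCDE")
        mats = []
        for seed in (1, 2):
            out = resolve_polytomies(poly, seed=seed)
            assert out.is_binary()
            mats.append(vcv_from_tree(out, taxa).C)
        np.testing.assert_allclose(mats[0], mats[1], atol=1e-10)
        np.testing.assert_allclose(mats[0], vcv_from_tree(poly, taxa).C, atol=1e-10)


class TestPrune:
    def test_keep_all_is_identity(self, three_taxon_tree):
        out = prune_to_taxa(three_taxon_tree, ["A", "B", "C"])
        np.testing.assert_allclose(
            vcv_from_tree(out, ["A", "B", "C"]).C,
            vcv_from_tree(three_taxon_tree, ["A", "B", "C"]).C,
        )

    def test_hand_example_depths_preserved(self, three_taxon_tree):
        out = prune_to_taxa(three_taxon_tree, ["A", "C"])
        assert out.depths() == {"A": 2.0, "C": 2.0}
        c = vcv_from_tree(out, ["A", "C"]).C
        np.testing.assert_allclose(c, [[2.0, 0.0], [0.0, 2.0]])

    def test_shared_path_above_pruned_mrca_is_kept(self, three_taxon_tree):
        out = prune_to_taxa(three_taxon_tree, ["A", "B"])
        c = vcv_from_tree(out, ["A", "B"]).C
        np.testing.assert_allclose(c, [[2.0, 1.0], [1.0, 2.0]])

    def test_unknown_taxon_listed_in_error(self, three_taxon_tree):
        with pytest.raises(ValueError, match="Z"):
            prune_to_taxa(three_taxon_tree, ["A", "Z"])

    def test_subset_of_larger_tree_covariance_invariant(self, extant_tree):
        keep = sorted(extant_tree.tip_labels)[:20]
        sub = prune_to_taxa(extant_tree, keep)
        assert sorted(sub.tip_labels) == keep
        np.testing.assert_allclose(
            vcv_from_tree(sub, keep).C, vcv_from_tree(extant_tree, keep).C,
            atol=1e-10,
        )


class TestVcv:
    def test_hand_computation(self, three_taxon_tree):
        cov = vcv_from_tree(three_taxon_tree, ["A", "B", "C"])
        np.testing.assert_allclose(
            cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12
        )

    def test_star_tree_is_diagonal(self):
        star = parse_newick("(A:1,B:2,C:3):0;")
        c = vcv_from_tree(star, ["A", "B", "C"]).C
        np.testing.assert_allclose(c, np.diag([1.0, 2.0, 3.0]))

    def test_unknown_taxon_raises(self, three_taxon_tree):
        with pytest.raises(ValueError):
            vcv_from_tree(three_taxon_tree, ["A", "Q"])

    @pytest.mark.parametrize("seed", range(100))
    def test_diagonal_matches_path_sum_oracle(self, seed):
        tree = simulate_tree(10, seed=seed)
        cov = vcv_from_tree(tree)
        oracle = tip_depths_dendropy(tree)
        np.testing.assert_allclose(
            np.diag(cov.C), [oracle[t] for t in cov.taxa], rtol=1e-10
        )

    def test_ultrametric_tree_has_equal_depths(self, extant_tree):
        d = np.diag(vcv_from_tree(extant_tree).C)
        assert np.ptp(d) <= 1e-8

    def test_offdiagonal_bounded_by_depths(self, extant_tree):
        C = vcv_from_tree(extant_tree).C
        d = np.diag(C)
        bound = np.minimum.outer(d, d)
        assert np.all(C <= bound + 1e-12)
        assert np.all(C >= -1e-12)
        np.testing.assert_allclose(C, C.T, atol=1e-12)


class TestLambdaTransform:
    def test_identity_at_one(self, three_taxon_tree):
        cov = vcv_from_tree(three_taxon_tree, ["A", "B", "C"])
        np.testing.assert_allclose(lambda_transform(cov, 1.0).V, cov.C)

    def test_star_limit_at_zero(self, three_taxon_tree):
        cov = vcv_from_tree(three_taxon_tree, ["A", "B", "C"])
        np.testing.assert_allclose(
            lambda_transform(cov, 0.0).V, np.diag(np.diag(cov.C))
        )

    def test_offdiagonal_scaling(self, three_taxon_tree):
        cov = vcv_from_tree(three_taxon_tree, ["A", "B", "C"])
        V = lambda_transform(cov, 0.64).V
        assert V[0, 1] == pytest.approx(0.64)
        assert V[0, 0] == pytest.approx(2.0)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, three_taxon_tree, lam):
        cov = vcv_from_tree(three_taxon_tree, ["A", "B", "C"])
        with pytest.raises(ValueError):
            lambda_transform(cov, lam)

    @pytest.mark.parametrize("seed", range(0, 100, 5))
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_positive_definite_on_random_trees(self, seed, lam):
        tree = simulate_tree(12, seed=seed)
        V = lambda_transform(vcv_from_tree(tree), lam).V
        np.linalg.cholesky(V)  # raises if not PD


def test_prune_resolve_order_commutes():
    poly = parse_newick("((A:1,B:1,C:1,D:1):1,(E:1.5,F:0.5):0.5):0;")
    keep = ["A", "B", "D", "E"]
    c1 = vcv_from_tree(prune_to_taxa(resolve_polytomies(poly, 5), keep), keep).C
    c2 = vcv_from_tree(resolve_polytomies(prune_to_taxa(poly, keep), 9), keep).C
    np.testing.assert_allclose(c1, c2, atol=1e-10)


def test_synonym_renaming():
    tree = parse_newick("(Palaeopropithecus_ingens:1,B:1):0;")
    out = tree.rename_tips({"Palaeopropithecus ingens": "Paleopropithecus ingens"})
    assert "Paleopropithecus ingens" in out.tip_labels
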