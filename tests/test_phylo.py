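import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from tephylo.datasets import study_tree_newick
from tephylo.phylo import (
    NewickParseError,
    Phylogeny,
    PhylogenyError,
    apply_lambda,
    parse_newick,
    read_tagged_newick,
)


class TestParse:
    def test_study_tree_tips_and_lengths(self, drosophila_tree):
        t = drosophila_tree
        assert t.n_tips == 12
        assert t.branch_length("dsim") == pytest.approx(0.02120277, abs=0)
        assert t.branch_length("dwil") == pytest.approx(0.69140554, abs=0)

    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:1);")
        assert t.tip_labels == ["A", "B"]
        assert t.branch_length("A") == 1.0

    def test_unbalanced_string_raises_with_offset(self):
        with pytest.raises(NewickParseError, match="column"):
            parse_newick("(A:1,B:1")

    def test_missing_branch_length_raises(self):
        with pytest.raises(PhylogenyError, match="missing branch length"):
            parse_newick("(A:1,B);")

    def test_duplicate_tips_raise(self):
        with pytest.raises((NewickParseError, PhylogenyError)):
            parse_newick("(A:1,A:2);")

    def test_roundtrip_identity(self, drosophila_tree):
        """parse(serialize(T)) preserves topology and branch lengths at full
        printed precision."""
        t2 = parse_newick(drosophila_tree.to_newick())
        assert t2.tip_labels == drosophila_tree.tip_labels
        for tip in t2.tip_labels:
            assert t2.branch_length(tip) == drosophila_tree.branch_length(tip)
        pd.testing.assert_frame_equal(
            t2.bm_covariance(), drosophila_tree.bm_covariance()
        )


class TestPrune:
    def test_subgroup_path_lengths_preserved(self, drosophila_tree):
        keep = ["dmel", "dsim", "dsec", "dyak", "dere"]
        sub = drosophila_tree.prune(keep)
        assert sorted(sub.tip_labels) == sorted(keep)
        # independent oracle: dendropy patristic distances on the full tree
        full = dendropy.Tree.get(
            data=study_tree_newick(), schema="newick", preserve_underscores=True
        )
        pdm = full.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in full.taxon_namespace}
        sub_dp = dendropy.Tree.get(
            data=sub.to_newick(), schema="newick", preserve_underscores=True
        )
        pdm_sub = sub_dp.phylogenetic_distance_matrix()
        taxa_sub = {t.label: t for t in sub_dp.taxon_namespace}
        for a in keep:
            for b in keep:
                if a >= b:
                    continue
                assert pdm_sub.patristic_distance(
                    taxa_sub[a], taxa_sub[b]
                ) == pytest.approx(
                    pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-12
                )

    def test_dsim_dsec_distance(self, drosophila_tree):
        sub = drosophila_tree.prune(["dsim", "dsec"])
        total = sub.branch_length("dsim") + sub.branch_length("dsec")
        assert total == pytest.approx(0.02120277 + 0.02358723, abs=1e-12)

    def test_prune_to_all_tips_is_identity(self, drosophila_tree):
        sub = drosophila_tree.prune(drosophila_tree.tip_labels)
        pd.testing.assert_frame_equal(
            sub.bm_covariance(), drosophila_tree.bm_covariance()
        )

    def test_single_tip_and_unknown_label_raise(self, drosophila_tree):
        with pytest.raises(PhylogenyError):
            drosophila_tree.prune(["dmel"])
        with pytest.raises(PhylogenyError, match="dxyz"):
            drosophila_tree.prune(["dmel", "dxyz"])


class TestCovariance:
    def test_hand_example(self, three_tip_tree):
        V = three_tip_tree.bm_covariance()
        assert V.loc["A", "A"] == 2.0
        assert V.loc["A", "B"] == 1.0
        assert V.loc["A", "C"] == 0.0
        assert V.loc["C", "C"] == 2.0

    def test_star_tree_is_diagonal(self, star_tree):
        V = star_tree.bm_covariance()
        assert np.allclose(V.to_numpy(), np.eye(3))

    def test_study_tree_shared_path(self, drosophila_tree):
        # V(dsim, dsec) = summed internal branches above their MRCA,
        # recomputed independently by walking the printed Newick string
        expected = 0.02898348 + 0.06713426 + 0.43736490 + 0.11949656
        V = drosophila_tree.bm_covariance()
        assert V.loc["dsim", "dsec"] == pytest.approx(expected, abs=1e-12)

    def test_psd_and_diag_dominance(self, drosophila_tree):
        V = drosophila_tree.bm_covariance().to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-10
        d = np.diag(V)
        assert (V <= np.minimum.outer(d, d) + 1e-15).all()

    def test_diag_equals_root_to_tip(self, drosophila_tree):
        V = drosophila_tree.bm_covariance()
        rtl = drosophila_tree.root_to_tip_lengths()
        assert (np.diag(V.to_numpy()) == rtl.to_numpy()).all()

    def test_dmel_root_to_tip(self, drosophila_tree):
        expected = 0.05989652 + 0.06713426 + 0.43736490 + 0.11949656
        assert drosophila_tree.root_to_tip_lengths()["dmel"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_non_ultrametric_lengths(self):
        t = parse_newick("(A:3,B:1);")
        rtl = t.root_to_tip_lengths()
        assert rtl["A"] == 3.0 and rtl["B"] == 1.0


class TestLambda:
    def test_identity_at_one(self, drosophila_tree):
        V = drosophila_tree.bm_covariance()
        pd.testing.assert_frame_equal(apply_lambda(V, 1.0), V)

    def test_zero_gives_star(self, drosophila_tree):
        V = apply_lambda(drosophila_tree.bm_covariance(), 0.0)
        A = V.to_numpy()
        assert np.allclose(A - np.diag(np.diag(A)), 0.0)

    def test_half_scales_off_diagonal(self, three_tip_tree):
        V = apply_lambda(three_tip_tree.bm_covariance(), 0.5)
        assert V.loc["A", "B"] == 0.5
        assert V.loc["A", "A"] == 2.0

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range_rejected(self, three_tip_tree, lam):
        with pytest.raises(PhylogenyError):
            apply_lambda(three_tip_tree.bm_covariance(), lam)


class TestContrasts:
    def test_cherry_formula(self):
        t = parse_newick("(A:1,B:1);")
        cs = t.independent_contrasts({"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert cs.values[0] == pytest.approx(2.0 / math.sqrt(2.0))

    def test_constant_trait_gives_zero(self, drosophila_tree):
        cs = drosophila_tree.independent_contrasts(
            {t: 5.0 for t in drosophila_tree.tip_labels}
        )
        assert np.allclose(cs.values, 0.0)
        assert len(cs) == 11  # n - 1 after resolving the root trifurcation
        assert (cs.divisors > 0).all()

    def test_hand_recursion_three_tips(self, three_tip_tree):
        # cherry (A,B): contrast 2/sqrt(2), ancestor value 1, adjusted edge
        # 1 + 0.5; root contrast (1-1)/sqrt(1.5+2) = 0
        cs = three_tip_tree.independent_contrasts({"A": 2.0, "B": 0.0, "C": 1.0})
        vals = sorted(np.abs(cs.values))
        assert vals[1] == pytest.approx(2.0 / math.sqrt(2.0))
        assert vals[0] == pytest.approx(0.0, abs=1e-15)
        assert sorted(cs.divisors) == pytest.approx(
            sorted([math.sqrt(2.0), math.sqrt(3.5)])
        )

    def test_missing_trait_names_tip(self, three_tip_tree):
        with pytest.raises(PhylogenyError, match="C"):
            three_tip_tree.independent_contrasts({"A": 1.0, "B": 2.0})

    def test_zero_length_cherry_rejected(self):
        t = parse_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(PhylogenyError, match="zero-length cherry"):
            t.independent_contrasts({"A": 1.0, "B": 2.0, "C": 0.0})

    def test_sum_of_squares_matches_gls_quadratic_form(self, rng, four_tip_tree):
        """Felsenstein/GLS equivalence: sum of squared standardized contrasts
        equals y'V^-1 y minus the GLS mean term."""
        for tree in [four_tip_tree, parse_newick(study_tree_newick())]:
            y = pd.Series(
                rng.standard_normal(tree.n_tips), index=tree.tip_labels
            )
            cs = tree.independent_contrasts(y)
            V = tree.bm_covariance().to_numpy()
            Vi = np.linalg.inv(V)
            one = np.ones(tree.n_tips)
            yv = y.to_numpy()
            mu = (one @ Vi @ yv) / (one @ Vi @ one)
            q = (yv - mu * one) @ Vi @ (yv - mu * one)
            assert np.sum(cs.values**2) == pytest.approx(q, abs=1e-8)

    def test_polytomy_resolution_preserves_covariance(self, star_tree):
        res = star_tree.resolve_polytomies()
        assert not res.has_polytomy()
        pd.testing.assert_frame_equal(
            res.bm_covariance().loc[star_tree.tip_labels, star_tree.tip_labels],
            star_tree.bm_covariance(),
        )


class TestPathLabeling:
    def test_terminal_branch_only(self, drosophila_tree):
        parent = drosophila_tree.parent_id("dmel")
        lab = drosophila_tree.label_path("dmel", parent)
        assert lab.foreground == frozenset({"dmel"})
        assert "dmel" not in lab.background

    def test_partition_and_connectivity(self, drosophila_tree):
        anc = drosophila_tree.mrca(["dmel", "dana"])
        lab = drosophila_tree.label_path("dmel", anc)
        all_edges = lab.foreground | lab.background
        assert not (lab.foreground & lab.background)
        n_edges = len(drosophila_tree.node_ids) - 1  # every node but the root
        assert len(all_edges) == n_edges
        # foreground is the connected chain of parents from the tip
        cur = "dmel"
        chain = set()
        while cur != anc:
            chain.add(cur)
            cur = drosophila_tree.parent_id(cur)
        assert lab.foreground == frozenset(chain)

    def test_excludes_branch_above_ancestor(self, drosophila_tree):
        # foreground stops below the ancestor: the edge joining the ancestor
        # to its own parent stays background
        anc = drosophila_tree.mrca(["dmel", "dsim"])
        lab = drosophila_tree.label_path("dmel", anc)
        assert anc not in lab.foreground
        assert anc in lab.background

    def test_non_ancestor_raises(self, drosophila_tree):
        anc = drosophila_tree.mrca(["dmoj", "dvir"])
        with pytest.raises(PhylogenyError):
            drosophila_tree.label_path("dmel", anc)

    def test_tagged_newick_roundtrip(self, drosophila_tree):
        anc = drosophila_tree.mrca(["dmel", "dana"])
        lab = drosophila_tree.label_path("dmel", anc)
        clean, fg = read_tagged_newick(lab.tagged_newick)
        assert fg == lab.foreground
        assert clean.tip_labels == drosophila_tree.tip_labels
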