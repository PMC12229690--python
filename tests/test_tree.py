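import numpy as np
import pytest

import phylopred as pp
from phylopred.tree import TreeError

from conftest import brute_force_vcv


class TestNewickIO:
    def test_three_tip_read(self):
        t = pp.read_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.height == pytest.approx(2.0)

    def test_absent_lengths_recorded(self):
        t = pp.read_newick("(A,B);")
        assert t.n_tips == 2
        assert not t.has_branch_lengths
        with pytest.raises(TreeError):
            pp.vcv(t)

    def test_round_trip_preserves_lengths(self):
        text = "((A:1,B:1):1,C:2);"
        t = pp.read_newick(text)
        t2 = pp.read_newick(pp.write_newick(t))
        c1, c2 = pp.vcv(t), pp.vcv(t2)
        assert c1.taxon_order == c2.taxon_order
        np.testing.assert_allclose(c1.V, c2.V)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            pp.read_newick("((A:1,A:1):1,C:2);")

    def test_malformed_input_rejected(self):
        with pytest.raises(TreeError):
            pp.read_newick("((A:1,B:1):1,C:2")


class TestVcv:
    def test_two_tip_no_shared_path(self):
        cov = pp.vcv(pp.read_newick("(A:1,B:1);"))
        np.testing.assert_allclose(cov.V, np.eye(2))

    def test_three_tip_path_sums(self, three_tip):
        cov = pp.vcv(three_tip)
        order = {t: i for i, t in enumerate(cov.taxon_order)}
        V = cov.V
        assert V[order["A"], order["B"]] == pytest.approx(0.5)
        assert V[order["A"], order["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(V), 1.0)

    def test_matches_path_enumeration_oracle_20_tips(self, random_tree_factory):
        t = random_tree_factory(n_tips=20, seed=7, ext_rate=0.3)
        cov = pp.vcv(t)
        V_ref, labels = brute_force_vcv(t)
        assert cov.taxon_order == labels
        np.testing.assert_allclose(cov.V, V_ref, atol=1e-12)

    def test_matches_oracle_on_many_random_small_trees(self, random_tree_factory):
        for seed in range(200):
            t = random_tree_factory(n_tips=3 + seed % 13, seed=seed, ext_rate=0.2 * (seed % 2))
            cov = pp.vcv(t)
            V_ref, labels = brute_force_vcv(t)
            assert cov.taxon_order == labels
            np.testing.assert_allclose(cov.V, V_ref, atol=1e-10)

    def test_ultrametric_diagonal_is_height(self, random_tree_factory):
        t = random_tree_factory(n_tips=30, seed=3)
        cov = pp.vcv(t)
        np.testing.assert_allclose(np.diag(cov.V), t.height, atol=1e-10)


class TestTransforms:
    def test_standardize_height_halves(self):
        t = pp.read_newick("((A:1,B:1):1,C:2);")
        s = pp.standardize_height(t)
        assert s.height == pytest.approx(1.0)
        np.testing.assert_allclose(pp.vcv(s).V, pp.vcv(t).V / 2.0)

    def test_standardize_height_identity(self, three_tip):
        s = pp.standardize_height(three_tip)
        np.testing.assert_allclose(pp.vcv(s).V, pp.vcv(three_tip).V)

    def test_extinct_tip_rescales_linearly(self):
        # extinct tip at depth 0.6 of a height-2 tree lands at depth 0.3
        t = pp.read_newick("((A:1.5,B:1.5):0.5,F:0.6);")
        s = pp.standardize_height(t)
        assert s.tip_depths()["F"] == pytest.approx(0.3)

    def test_standardize_total_length(self, three_tip):
        s = pp.standardize_total_length(three_tip)
        total = sum(
            nd.edge.length
            for nd in s.dtree.preorder_node_iter()
            if nd is not s.dtree.seed_node
        )
        assert total == pytest.approx(1.0)
        # proportions preserved
        np.testing.assert_allclose(pp.vcv(s).V * 2.5, pp.vcv(three_tip).V)

    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 1.0])
    def test_lambda_scales_offdiagonal_only(self, three_tip, lam):
        cov = pp.vcv(three_tip)
        out = pp.transform_lambda(cov, lam)
        np.testing.assert_allclose(np.diag(out.V), np.diag(cov.V))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(out.V[off], cov.V[off] * lam)

    def test_lambda_domain_error(self, three_tip):
        cov = pp.vcv(three_tip)
        with pytest.raises(ValueError):
            pp.transform_lambda(cov, 1.2)
        with pytest.raises(ValueError):
            pp.transform_lambda(cov, -0.1)

    def test_kappa_identity_and_zero(self, three_tip):
        same = pp.transform_kappa(three_tip, 1.0)
        np.testing.assert_allclose(pp.vcv(same).V, pp.vcv(three_tip).V)
        ones = pp.transform_kappa(three_tip, 0.0)
        lengths = [
            nd.edge.length
            for nd in ones.dtree.preorder_node_iter()
            if nd is not ones.dtree.seed_node
        ]
        assert lengths == [1.0] * len(lengths)

    def test_kappa_power(self):
        t = pp.read_newick("(A:0.25,B:0.25);")
        out = pp.transform_kappa(t, 0.5)
        assert out.tip_depths()["A"] == pytest.approx(0.5)


class TestDescriptors:
    def test_terminal_and_mean_path(self, three_tip):
        terminal, mean_path, height = pp.tree_descriptors(three_tip)
        assert terminal["A"] == pytest.approx(0.5)
        assert terminal["C"] == pytest.approx(1.0)
        assert mean_path == pytest.approx(1.0)
        assert height == pytest.approx(1.0)

    def test_mean_path_matches_enumeration(self, random_tree_factory):
        t = random_tree_factory(n_tips=10, seed=11, ext_rate=0.4)
        _, mean_path, _ = pp.tree_descriptors(t)
        V_ref, _ = brute_force_vcv(t)
        assert mean_path == pytest.approx(np.mean(np.diag(V_ref)), abs=1e-10)


class TestShapeMetrics:
    def test_balanced_colless_zero(self):
        assert pp.shape_metrics(pp.balanced_tree(8)).colless == 0

    @pytest.mark.parametrize("n", range(3, 13))
    def test_pectinate_colless_closed_form(self, n):
        sm = pp.shape_metrics(pp.pectinate_tree(n))
        assert sm.colless == (n - 1) * (n - 2) // 2

    def test_balanced4_sackin(self):
        assert pp.shape_metrics(pp.balanced_tree(4)).sackin == 8

    def test_stemminess_in_unit_interval(self, random_tree_factory):
        for seed in range(5):
            sm = pp.shape_metrics(random_tree_factory(n_tips=12, seed=seed))
            assert 0.0 <= sm.stemminess <= 1.0

    def test_polytomy_rejected_in_strict_mode(self):
        t = pp.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="polytomy"):
            pp.shape_metrics(t, strict=True)
        sm = pp.shape_metrics(t, strict=False)
        assert sm.sackin == 3


class TestGraftTip:
    def tall_tree(self):
        # ultrametric, height 20: ((A:12,B:12):8,(C:15,D:15):5);
        return pp.read_newick("((A:12,B:12):8,(C:15,D:15):5);")

    def test_sister_graft_terminal_length(self):
        t = self.tall_tree()
        out = pp.graft_tip(t, anchor="A", divergence_age=10.0, tip_age=2.0, label="F")
        terminal, _, _ = pp.tree_descriptors(out)
        assert terminal["F"] == pytest.approx(8.0)
        # fossil tip depth corresponds to age 2 before present
        assert out.tip_depths()["F"] == pytest.approx(18.0)

    def test_other_paths_unchanged(self):
        t = self.tall_tree()
        out = pp.graft_tip(t, anchor="A", divergence_age=10.0, tip_age=2.0, label="F")
        keep = ["A", "B", "C", "D"]
        before = pp.vcv(t).restrict(keep)
        after = pp.vcv(out).restrict(keep)
        np.testing.assert_allclose(after.V, before.V, atol=1e-12)

    def test_polytomy_graft_at_clade_base(self):
        t = self.tall_tree()
        # MRCA(C, D) sits at age 15
        out = pp.graft_tip(t, anchor=["C", "D"], divergence_age=15.0, tip_age=0.0,
                           label="E")
        assert out.tip_depths()["E"] == pytest.approx(20.0)
        assert "E" in out.extant_tips()

    def test_vcv_after_graft_matches_oracle(self):
        t = self.tall_tree()
        out = pp.graft_tip(t, anchor="C", divergence_age=11.0, tip_age=3.0, label="F")
        V_ref, labels = brute_force_vcv(out)
        cov = pp.vcv(out)
        assert cov.taxon_order == labels
        np.testing.assert_allclose(cov.V, V_ref, atol=1e-12)

    def test_divergence_outside_stem_rejected(self):
        t = self.tall_tree()
        with pytest.raises(TreeError, match="outside"):
            pp.graft_tip(t, anchor="A", divergence_age=25.0, tip_age=2.0, label="F")
        with pytest.raises(TreeError):
            pp.graft_tip(t, anchor="A", divergence_age=10.0, tip_age=12.0, label="F")
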