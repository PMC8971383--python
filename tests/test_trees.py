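"""Tree parsing, Brownian covariance, and rate rescaling."""

import numpy as np
import pytest

from paleobrain.trees import NewickError, parse_newick

from conftest import random_bd_tree


def brute_force_vcv(tree):
    """Independent oracle: MRCA depth for every tip pair by walking
    root-to-tip paths node by node."""
    paths = {}
    for row, tip in enumerate(tree.tip_indices):
        path = []
        node = tip
        while node != -1:
            path.append(node)
            node = tree.parent[node]
        paths[row] = list(reversed(path))  # root first
    n = tree.n_tips
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = 0.0
            for a, b in zip(paths[i], paths[j]):
                if a != b:
                    break
                shared = tree.node_depths[a]
            out[i, j] = shared
    return out


class TestParsing:
    def test_contemporaneous_tree(self, three_tip):
        assert three_tip.n_tips == 3
        assert three_tip.height == 2.0
        assert three_tip.fossil_tips() == []

    def test_fossil_tip_flagged(self, fossil_tree):
        assert fossil_tree.height == 2.0
        assert fossil_tree.fossil_tips() == ["B"]
        depths = dict(zip(fossil_tree.tip_labels, fossil_tree.tip_depths))
        assert depths["B"] == pytest.approx(1.5)

    def test_polytomy_resolved_binary_with_zero_branch(self):
        tree = parse_newick("((A:1,B:1,C:1):1,D:2);")
        # binary: every internal node has exactly 2 children
        n_children = {}
        for i, p in enumerate(tree.parent):
            if p >= 0:
                n_children[p] = n_children.get(p, 0) + 1
        assert set(n_children.values()) == {2}
        assert (tree.branch_lengths == 0).sum() == 1
        # covariance unchanged by the zero-length resolution
        np.testing.assert_allclose(tree.vcv().matrix, brute_force_vcv(tree))

    def test_malformed_newick(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:1:1,C;")

    def test_missing_branch_length(self):
        with pytest.raises(NewickError, match="branch length"):
            parse_newick("((A:1,B):1,C:2);")

    def test_duplicate_tips(self):
        with pytest.raises(NewickError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_newick_round_trip(self):
        tree = random_bd_tree(40, seed=3)
        back = parse_newick(tree.to_newick())
        assert back.tip_labels == tree.tip_labels
        np.testing.assert_allclose(
            back.branch_lengths, tree.branch_lengths, rtol=1e-9
        )


class TestVcv:
    def test_star_tree_is_diagonal(self):
        tree = parse_newick("(A:3,B:3,C:3,D:3);")
        np.testing.assert_allclose(tree.vcv().matrix, 3.0 * np.eye(4))

    def test_hand_checked_three_tip(self, three_tip):
        v = three_tip.vcv()
        expect = {("A", "A"): 2, ("B", "B"): 2, ("C", "C"): 2,
                  ("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0}
        idx = {t: i for i, t in enumerate(v.tip_order)}
        for (a, b), val in expect.items():
            assert v.matrix[idx[a], idx[b]] == pytest.approx(val)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_mrca_oracle(self, seed):
        tree = random_bd_tree(20, seed=seed)
        np.testing.assert_allclose(
            tree.vcv().matrix, brute_force_vcv(tree), atol=1e-12
        )

    def test_diag_equals_tip_depths(self):
        tree = random_bd_tree(30, seed=9, death_rate=0.4)
        np.testing.assert_allclose(np.diag(tree.vcv().matrix), tree.tip_depths)

    def test_reorder_permutes_rows_and_columns(self, three_tip):
        v = three_tip.vcv()
        perm = ["C", "A", "B"]
        vp = v.reorder(perm)
        idx = [v.tip_order.index(t) for t in perm]
        np.testing.assert_allclose(vp.matrix, v.matrix[np.ix_(idx, idx)])


class TestRescale:
    def test_equal_rates_identity(self, three_tip):
        out = three_tip.rescale_by_rates(np.full(4, 0.7))
        np.testing.assert_allclose(
            out.branch_lengths, three_tip.branch_lengths, rtol=1e-12
        )

    def test_doubled_rate_doubles_relative_share(self):
        tree = parse_newick("((B:1,C:1)N:1,A:1);")
        rates = {"A": 2.0, "B": 1.0, "C": 1.0, "N": 1.0}
        out = tree.rescale_by_rates(rates)
        lens = dict(zip(out.branch_ids, out.branch_lengths))
        # hand-computed: scaled (2,1,1,1) renormalized to total 4 -> x 4/5
        assert lens["A"] == pytest.approx(1.6, rel=1e-10)
        assert lens["B"] == pytest.approx(0.8, rel=1e-10)
        assert out.total_branch_length == pytest.approx(4.0, rel=1e-10)

    def test_sign_of_rate_irrelevant(self, three_tip):
        r = np.array([1.0, -1.0, 2.0, -2.0])
        a = three_tip.rescale_by_rates(r)
        b = three_tip.rescale_by_rates(np.abs(r))
        np.testing.assert_allclose(a.branch_lengths, b.branch_lengths)

    def test_total_length_conserved(self):
        tree = random_bd_tree(200, seed=4)
        rng = np.random.default_rng(0)
        out = tree.rescale_by_rates(rng.normal(size=len(tree.branch_ids)))
        assert out.total_branch_length == pytest.approx(
            tree.total_branch_length, rel=1e-10
        )

    def test_preserve_height_option(self):
        tree = random_bd_tree(50, seed=6)
        rng = np.random.default_rng(1)
        out = tree.rescale_by_rates(
            rng.normal(size=len(tree.branch_ids)), preserve="height"
        )
        assert out.height == pytest.approx(tree.height, rel=1e-10)

    def test_all_zero_rates_rejected(self, three_tip):
        with pytest.raises(ValueError, match="degenerate"):
            three_tip.rescale_by_rates(np.zeros(4))
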