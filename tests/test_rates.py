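"""Phylogenetic ridge regression rates and the rate-shift randomization test."""

import numpy as np
import pandas as pd
import pytest

from paleobrain.rates import estimate_rates, path_matrix, shift_test
from paleobrain.synthetic import SimulationConfig, simulate_dataset, simulate_tree, simulate_traits
from paleobrain.trees import parse_newick

from conftest import random_bd_tree


def ridge_closed_form(tree, y, lam):
    """Independent oracle: explicit-inverse ridge with unpenalized root."""
    L = path_matrix(tree).to_numpy()
    A = np.hstack([np.ones((len(y), 1)), L])
    D = np.eye(A.shape[1])
    D[0, 0] = 0.0
    coef = np.linalg.inv(A.T @ A + lam * D) @ (A.T @ y)
    return coef[0], coef[1:]


class TestPathMatrix:
    def test_two_tip_tree(self):
        tree = parse_newick("(A:1,B:2);")
        pm = path_matrix(tree)
        assert pm.loc["A", "A"] == 1.0
        assert pm.loc["B", "B"] == 2.0
        assert pm.loc["A", "B"] == 0.0

    def test_three_tip_tree_internal_branch(self, three_tip):
        pm = path_matrix(three_tip)
        internal = [c for c in pm.columns if c not in ("A", "B", "C")][0]
        assert pm.loc["A", internal] == 1.0
        assert pm.loc["C", internal] == 0.0
        assert pm.loc["C", "C"] == 2.0

    def test_row_sums_equal_tip_depths(self):
        tree = random_bd_tree(60, seed=13, death_rate=0.35)
        pm = path_matrix(tree)
        np.testing.assert_allclose(pm.sum(axis=1).to_numpy(), tree.tip_depths)


class TestEstimateRates:
    def test_constant_trait_gives_zero_rates(self):
        tree = random_bd_tree(25, seed=1)
        y = pd.Series(3.7, index=tree.tip_labels)
        br = estimate_rates(tree, y, lam=1.0)
        assert br.root_estimate == pytest.approx(3.7, abs=1e-8)
        np.testing.assert_allclose(br.branch_rates.to_numpy(), 0.0, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.01, 1.0, 100.0])
    def test_matches_closed_form_at_fixed_lambda(self, lam):
        tree = random_bd_tree(30, seed=2)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=tree.n_tips), index=tree.tip_labels)
        br = estimate_rates(tree, y, lam=lam)
        root, b = ridge_closed_form(tree, y.to_numpy(), lam)
        assert br.root_estimate == pytest.approx(root, abs=1e-8)
        np.testing.assert_allclose(br.branch_rates.to_numpy(), b, atol=1e-8)

    def test_large_lambda_shrinks_rates_to_zero_and_root_to_mean(self):
        tree = random_bd_tree(20, seed=3)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(2.0, 1.0, tree.n_tips), index=tree.tip_labels)
        br = estimate_rates(tree, y, lam=1e10)
        assert np.max(np.abs(br.branch_rates)) < 1e-6
        assert br.root_estimate == pytest.approx(y.mean(), abs=1e-6)

    def test_doubled_branch_lengths_halve_rates(self):
        tree = random_bd_tree(20, seed=6)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=tree.n_tips), index=tree.tip_labels)
        doubled = tree.with_branch_lengths(tree.branch_lengths * 2.0)
        b1 = estimate_rates(tree, y, lam=1e-10).branch_rates.to_numpy()
        b2 = estimate_rates(doubled, y, lam=1e-10).branch_rates.to_numpy()
        np.testing.assert_allclose(b2, b1 / 2, atol=1e-4 * np.max(np.abs(b1)))

    def test_loocv_lambda_on_grid(self):
        tree = random_bd_tree(25, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=tree.n_tips), index=tree.tip_labels)
        br = estimate_rates(tree, y)
        assert br.lam > 0 and br.loocv_error is not None

    def test_misaligned_trait_rejected(self, three_tip):
        with pytest.raises(KeyError):
            estimate_rates(three_tip, pd.Series({"A": 1.0, "B": 2.0}))

    def test_fast_clade_recovered(self):
        """One clade evolving 10x faster shows larger mean |tip rate| inside
        than outside in nearly all replicates."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=10_000 + seed,
                n_tips=50,
                n_orders=4,
                bm_sigma2=0.05,
                rate_shift_clades={"order_01": 10.0},
            )
            tree = simulate_tree(cfg)
            table, truth = simulate_traits(tree, cfg)
            sp = table.set_index("species")
            br = estimate_rates(tree, sp["log10_endocast"], predictor=sp["log10_body"])
            inside = sp["order"] == "order_01"
            mean_in = np.abs(br.tip_rates[inside.to_numpy()]).mean()
            mean_out = np.abs(br.tip_rates[~inside.to_numpy()]).mean()
            hits += mean_in > mean_out
        assert hits >= 0.9 * n_rep


class TestShiftTest:
    @pytest.fixture
    def rates_and_status(self):
        ds = simulate_dataset(SimulationConfig(seed=21, n_tips=80))
        sp = ds.table.set_index("species")
        br = estimate_rates(ds.tree, sp["log10_endocast"], predictor=sp["log10_body"])
        return br, sp["status"]

    def test_reproducible_given_seed(self, rates_and_status):
        br, status = rates_and_status
        a = shift_test(br, status, n_permutations=500, seed=42)
        b = shift_test(br, status, n_permutations=500, seed=42)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_diffs, b.null_diffs)

    def test_relabeling_symmetry(self, rates_and_status):
        br, status = rates_and_status
        flipped = status.map({"extant": "extinct", "extinct": "extant"})
        a = shift_test(br, status, n_permutations=500, seed=7)
        b = shift_test(br, flipped, n_permutations=500, seed=7)
        assert a.p_value == b.p_value
        assert a.observed_diff == pytest.approx(-b.observed_diff)

    def test_p_in_unit_interval_with_add_one(self, rates_and_status):
        br, status = rates_and_status
        res = shift_test(br, status, n_permutations=99, seed=0)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_single_level_status_rejected(self, rates_and_status):
        br, status = rates_and_status
        with pytest.raises(ValueError):
            shift_test(br, pd.Series("extant", index=status.index), seed=0)
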