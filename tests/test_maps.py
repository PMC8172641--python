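"""Duplication mapping, Fisher comparison, resampling, BD rate estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from wgdkit.maps import (
    LadderError,
    LadderSpec,
    NullModel,
    estimate_bd_rates,
    fisher_compare,
    make_ladder_tree,
    map_duplications,
    maps_table,
    resample_percentages,
    run_null,
    run_positive,
    _counts_loglik_per_pattern,
)
from wgdkit.simulate import BDParams, WGDEvent, simulate_gene_counts, simulate_tree_set
from wgdkit.trees import read_newick


class TestLadderSpec:
    def test_from_tree_recovers_order(self, ladder6):
        tree, _ = ladder6
        spec = LadderSpec.from_tree(tree, ["og"])
        assert spec.ingroup == ["t1", "t2", "t3", "t4", "t5"]
        assert spec.node_names == ["N1", "N2", "N3", "N4"]
        assert spec.node_taxa("N2") == frozenset({"t1", "t2", "t3"})

    def test_non_ladder_tree_rejected(self):
        tree = read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")
        with pytest.raises(LadderError, match="ladder"):
            LadderSpec.from_tree(tree, ["E"])

    def test_make_ladder_tree_ultrametric(self, ladder6):
        tree, _ = ladder6
        assert tree.is_ultrametric()
        assert tree.is_ladder()
        assert tree.height() == 150


class TestMapDuplications:
    def test_textbook_shared_duplication(self):
        ladder = LadderSpec(["B", "C"], ["A"])
        gt = read_newick("((B|1:1,C|1:1):1,(B|2:1,C|2:1):1,A|1:2);")
        totals, dups = map_duplications(gt, ladder)
        assert totals == {"N1": 1} and dups == {"N1": 1}

    def test_species_specific_duplication_not_shared(self):
        ladder = LadderSpec(["B", "C"], ["A"])
        gt = read_newick("(((B|1:1,B|2:1):1,C|1:2):1,A|1:3);")
        totals, dups = map_duplications(gt, ladder)
        assert totals == {"N1": 1} and dups == {"N1": 0}

    def test_forced_wgd_maps_to_its_node_only(self, ladder6):
        tree, ladder = ladder6
        wgd = WGDEvent("N2", 10.0, 1.0)
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [wgd], n=20, seed=3)
        for gt in trees:
            totals, dups = map_duplications(gt, ladder)
            assert dups["N2"] == 1
            assert dups["N1"] == dups["N3"] == dups["N4"] == 0

    def test_retained_copy_doubles_descendant_subtrees(self, ladder6):
        """A retained WGD copy adds subtrees, not spurious duplications, at
        nodes below the event."""
        tree, ladder = ladder6
        wgd = WGDEvent("N2", 10.0, 1.0)
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [wgd], n=5, seed=4)
        totals, dups = map_duplications(trees[0], ladder)
        assert totals["N1"] == 2 and dups["N1"] == 0

    def test_missing_outgroup_rejected(self, ladder6):
        _, ladder = ladder6
        gt = read_newick("((t1|1:1,t2|1:1):1,t3|1:2);")
        with pytest.raises(LadderError, match="outgroup"):
            map_duplications(gt, ladder)


class TestMapsTable:
    def test_no_wgd_zero_percent_everywhere(self, ladder6):
        tree, ladder = ladder6
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [], n=100, seed=1)
        res = maps_table(trees, ladder)
        assert (res.table["pct"] == 0).all()
        assert (res.table["subtree_total"] == 100).all()

    def test_full_retention_hundred_percent_at_node(self, ladder6):
        tree, ladder = ladder6
        wgd = WGDEvent("N2", 10.0, 1.0)
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [wgd], n=100, seed=2)
        res = maps_table(trees, ladder)
        assert res.table.loc["N2", "pct"] == 100.0
        assert res.table.drop("N2")["pct"].eq(0).all()

    def test_partial_retention_binomial(self, ladder6):
        """Retention 0.3 without birth/death: N2 percentage ~ Binomial(n, .3)."""
        tree, ladder = ladder6
        wgd = WGDEvent("N2", 10.0, 0.3)
        n = 3000
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [wgd], n=n, seed=5)
        res = maps_table(trees, ladder)
        shared = res.table.loc["N2", "shared_dups"]
        sigma = math.sqrt(n * 0.3 * 0.7)
        assert abs(shared - n * 0.3) < 3 * sigma

    def test_counts_bounded_by_totals(self, ladder6):
        tree, ladder = ladder6
        trees, _ = simulate_tree_set(
            tree, BDParams(0.004, 0.004), [], n=200,
            require_full_coverage=True, seed=6,
        )
        res = maps_table(trees, ladder)
        assert (res.table["shared_dups"] <= res.table["subtree_total"]).all()
        assert res.table["pct"].between(0, 100).all()

    def test_trees_without_coverage_skipped(self, ladder6):
        tree, ladder = ladder6
        trees, _ = simulate_tree_set(
            tree, BDParams(0.002, 0.002), [], n=50, seed=7
        )
        res = maps_table(trees, ladder)
        assert res.n_trees + res.n_skipped == 50


class TestNullPositive:
    def test_zero_rates_null_is_all_zero(self, ladder6):
        _, ladder = ladder6
        res = run_null(ladder, NullModel(BDParams(0, 0), 50), seed=1)
        assert (res.table["pct"] == 0).all()

    def test_fixed_seed_reproducible(self, ladder6):
        _, ladder = ladder6
        model = NullModel(BDParams(0.002, 0.002), 100)
        a = run_null(ladder, model, seed=3)
        b = run_null(ladder, model, seed=3)
        assert a.table.equals(b.table)

    def test_null_pct_increases_with_birth_rate(self, ladder6):
        _, ladder = ladder6
        lo = run_null(ladder, NullModel(BDParams(0.001, 0.001), 3000), seed=4)
        hi = run_null(ladder, NullModel(BDParams(0.004, 0.004), 3000), seed=4)
        assert (hi.table["pct"] > lo.table["pct"]).all()

    def test_positive_dominates_null_at_wgd_node(self, ladder6):
        _, ladder = ladder6
        model = NullModel(BDParams(0.001, 0.001), 300)
        null = run_null(ladder, model, seed=5)
        pos = run_positive(ladder, model, "N2", retention=1.0, seed=5)
        assert pos.table.loc["N2", "pct"] >= null.table.loc["N2", "pct"]

    def test_low_retention_rejected_by_default(self, ladder6):
        _, ladder = ladder6
        model = NullModel(BDParams(0.001, 0.001), 10)
        with pytest.raises(ValueError, match="retention"):
            run_positive(ladder, model, "N2", retention=0.1, seed=1)

    def test_unknown_wgd_node_rejected(self, ladder6):
        _, ladder = ladder6
        model = NullModel(BDParams(0.001, 0.001), 10)
        with pytest.raises(LadderError, match="unknown"):
            run_positive(ladder, model, "N9", retention=0.5, seed=1)


class TestResampling:
    def test_pool_equal_to_size_gives_zero_width(self, ladder6):
        tree, ladder = ladder6
        trees, _ = simulate_tree_set(
            tree, BDParams(0.002, 0.002), [], n=200,
            require_full_coverage=True, seed=8,
        )
        res = maps_table(trees, ladder)
        ci = resample_percentages(res, ladder, size=res.n_trees, reps=10, seed=1)
        assert np.allclose(ci["pct_lo"], ci["pct_hi"])
        assert np.allclose(ci["pct_lo"], res.table["pct"])

    def test_pool_smaller_than_size_is_error(self, ladder6):
        tree, ladder = ladder6
        trees, _ = simulate_tree_set(tree, BDParams(0, 0), [], n=10, seed=1)
        res = maps_table(trees, ladder)
        with pytest.raises(ValueError, match="smaller"):
            resample_percentages(res, ladder, size=1000, reps=10, seed=1)

    def test_ci_brackets_full_pool_percentage(self, ladder6):
        tree, ladder = ladder6
        wgd = WGDEvent("N2", 10.0, 0.3)
        trees, _ = simulate_tree_set(
            tree, BDParams(0.002, 0.002), [wgd], n=1500,
            require_full_coverage=True, seed=9,
        )
        res = maps_table(trees, ladder)
        ci = resample_percentages(res, ladder, size=1000, reps=100, seed=9)
        pct = res.table.loc["N2", "pct"]
        assert ci.loc["N2", "pct_lo"] <= pct <= ci.loc["N2", "pct_hi"]


from _oracles import hypergeom_tail


class TestFisher:
    def test_matches_hypergeometric_enumeration(self, ladder6):
        _, ladder = ladder6
        obs = pd.DataFrame(
            {"subtree_total": [100] * 4, "shared_dups": [30, 10, 5, 0],
             "pct": [30.0, 10.0, 5.0, 0.0]},
            index=ladder.node_names,
        )
        nul = pd.DataFrame(
            {"subtree_total": [100] * 4, "shared_dups": [10, 10, 5, 0],
             "pct": [10.0, 10.0, 5.0, 0.0]},
            index=ladder.node_names,
        )
        from wgdkit.maps import MapsResult

        f = fisher_compare(MapsResult(obs, 100), MapsResult(nul, 100))
        # one-sided p for the 2x2 margin equals the hypergeometric tail
        expected = hypergeom_tail(30, 40, 100, 200)
        assert f.loc["N1", "p"] == pytest.approx(expected, rel=1e-9)
        assert f.loc["N1", "significant"]

    def test_equal_counts_not_enriched(self, ladder6):
        _, ladder = ladder6
        t = pd.DataFrame(
            {"subtree_total": [100] * 4, "shared_dups": [20] * 4, "pct": [20.0] * 4},
            index=ladder.node_names,
        )
        from wgdkit.maps import MapsResult

        f = fisher_compare(MapsResult(t, 100), MapsResult(t.copy(), 100))
        assert (f["p"] >= 0.5).all()
        assert not f["significant"].any()

    def test_zero_total_gives_p_one(self, ladder6):
        _, ladder = ladder6
        obs = pd.DataFrame(
            {"subtree_total": [0, 100, 100, 100], "shared_dups": [0, 1, 1, 1],
             "pct": [0.0, 1.0, 1.0, 1.0]},
            index=ladder.node_names,
        )
        from wgdkit.maps import MapsResult

        f = fisher_compare(MapsResult(obs, 100), MapsResult(obs.copy(), 100))
        assert f.loc["N1", "p"] == 1.0


class TestBDRates:
    def test_recovery_within_twenty_percent(self, ladder6):
        tree, _ = ladder6
        lam = mu = 0.002
        counts = simulate_gene_counts(tree, BDParams(lam, mu), 3000, seed=1)
        bd, diag = estimate_bd_rates(counts, tree)
        assert bd.birth_rate == pytest.approx(lam, rel=0.2)
        assert bd.death_rate == pytest.approx(mu, rel=0.2)
        assert not diag["boundary"]

    def test_all_single_copy_pushes_rates_to_boundary(self, ladder6):
        tree, _ = ladder6
        counts = pd.DataFrame(
            np.ones((200, 6), dtype=int),
            columns=sorted(tree.leaf_labels()),
        )
        bd, diag = estimate_bd_rates(counts, tree)
        assert bd.birth_rate < 1e-4
        assert diag["boundary"]

    def test_likelihood_higher_at_truth_than_doubled_rates(self, ladder6):
        tree, _ = ladder6
        lam = mu = 0.002
        counts = simulate_gene_counts(tree, BDParams(lam, mu), 1500, seed=2)
        arr = counts.to_numpy(dtype=int)
        arr = arr[arr.sum(axis=1) > 0]
        patterns, weights = np.unique(arr, axis=0, return_counts=True)
        ll_true = float(
            weights @ _counts_loglik_per_pattern(patterns, tree, lam, mu, 100)
        )
        ll_double = float(
            weights @ _counts_loglik_per_pattern(patterns, tree, 2 * lam, 2 * mu, 100)
        )
        assert ll_true > ll_double
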