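"""Percolation operator, partitioned-phi, Monte Carlo, living-fossil-ness."""

import itertools
import math

import numpy as np
import pytest

import evoheritage as eh
from evoheritage.powerset import (
    indicator,
    partitioned_phi_mc_whole_tree,
    ed_ranking,
)

from conftest import all_vertex_subsets


def build(tree, rho):
    return eh.build_evoheritage_tree(tree, eh.StandardConditions(rho=rho))


class TestConnectionMeasures:
    def test_self_reachability_with_no_edges(self, cherry):
        assert eh.reachable_count(cherry, "a", frozenset(), {"a"}) == 1
        assert eh.indicator(cherry, "a", frozenset(), {"a"}) == 1

    def test_full_edge_set_counts_subtree_members(self):
        tree = eh.generate_yule_tree(7, seed=21)
        G = frozenset(tree.edges())
        X = frozenset(tree.tips())
        for v in tree.vertices():
            below = {u for u in tree.subtree_vertices(v) if u in X}
            assert eh.reachable_count(tree, v, G, X) == len(below)

    def test_missing_edge_blocks_reachability(self, cherry):
        G = frozenset(e for e in cherry.edges() if e != "a")
        assert eh.reachable_count(cherry, cherry.root, G, {"a"}) == 0
        assert eh.indicator(cherry, cherry.root, G, {"a", "b"}) == 1  # b still reached

    def test_indicator_empty_target(self, cherry):
        assert eh.indicator(cherry, "a", frozenset(cherry.edges()), frozenset()) == 0

    def test_fair_share_cherry(self, cherry):
        G = frozenset(cherry.edges())
        Y = frozenset({"a", "b"})
        assert eh.fair_share_ratio(cherry, cherry.root, G, {"a"}, Y) == 0.5
        assert eh.fair_share_ratio(cherry, cherry.root, G, Y, Y) == 1.0
        assert eh.fair_share_ratio(cherry, cherry.root, frozenset(), {"a"}, Y) == 0.0

    def test_fair_share_requires_nested_sets(self, cherry):
        with pytest.raises(ValueError):
            eh.fair_share_ratio(cherry, cherry.root, frozenset(), {"a"}, {"b"})


class TestKappaExact:
    def test_no_attrition_collapses_to_full_edge_set(self):
        tree = eh.generate_yule_tree(6, seed=22)
        et = build(tree, 0.0)
        X = frozenset(tree.tips()[:3])
        expected = sum(
            et.alpha[e]
            for e in tree.edges()
            if eh.indicator(tree, e, frozenset(tree.edges()), X)
        )
        assert eh.kappa_exact(et, indicator, (X,)) == pytest.approx(expected, abs=1e-12)

    def test_single_edge_hand_expansion(self):
        et = build(eh.parse_newick("(a:2);"), rho=0.5)
        # both retention outcomes reach the tip from itself: kappa = alpha
        assert eh.kappa_exact(et, indicator, (frozenset({"a"}),)) == pytest.approx(
            et.alpha["a"], abs=1e-14
        )

    def test_enumeration_cap_enforced(self):
        tree = eh.generate_yule_tree(30, seed=23)
        et = build(tree, 0.5)
        with pytest.raises(ValueError, match="Monte Carlo"):
            eh.kappa_exact(et, indicator, (frozenset(tree.tips()),), cap=10)

    def test_weights_sum_to_one(self):
        tree = eh.generate_yule_tree(6, seed=24)  # 11 edges with stem
        et = build(tree, 0.3)
        edges = tree.edges()
        total = 0.0
        for keep in itertools.product([False, True], repeat=len(edges)):
            w = 1.0
            for e, k in zip(edges, keep):
                w *= et.beta[e] if k else (1.0 - et.beta[e])
            total += w
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.1, 1.0])
    def test_matches_phi_on_small_trees(self, rho):
        for tree in eh.enumerate_tree_topologies(4):
            et = build(tree, rho)
            for X in all_vertex_subsets(tree):
                assert eh.phi_via_powerset(et, X) == pytest.approx(
                    eh.phi(et, X), abs=1e-10
                )

    def test_generic_callable_agrees_with_fast_path(self, caterpillar_stem):
        et = build(caterpillar_stem, 0.4)
        X = frozenset({"a", "c"})

        def slow_indicator(tree, v, G, S):
            return 1 if eh.reachable_count(tree, v, G, S) >= 1 else 0

        assert eh.kappa_exact(et, slow_indicator, (X,)) == pytest.approx(
            eh.kappa_exact(et, indicator, (X,)), abs=1e-12
        )


class TestPartitionedPhi:
    def test_symmetric_cherry_splits_evenly(self, cherry):
        et = build(cherry, 0.5)
        Y = frozenset({"a", "b"})
        total = eh.phi(et, Y)
        assert eh.partitioned_phi_exact(et, {"a"}, Y) == pytest.approx(
            total / 2, abs=1e-12
        )

    @pytest.mark.parametrize("rho", [0.01, 0.5])
    @pytest.mark.parametrize("seed", range(3))
    def test_partition_conservation(self, rho, seed):
        tree = eh.generate_yule_tree(5, seed=seed)
        et = build(tree, rho)
        Y = frozenset(tree.tips())
        total = sum(eh.partitioned_phi_exact(et, {x}, Y) for x in Y)
        assert total == pytest.approx(eh.phi(et, Y), abs=1e-10)

    def test_ed_limit(self):
        tree = eh.generate_yule_tree(5, seed=31)
        Y = frozenset(tree.tips())
        et = build(tree, 1e-8)
        su = eh.standardized_unit(eh.StandardConditions(rho=1e-8))
        ed = eh.evolutionary_distinctiveness(tree, Y)
        for x in Y:
            assert eh.partitioned_phi_exact(et, {x}, Y) / su == pytest.approx(
                ed[x], rel=1e-3
            )


class TestMonteCarlo:
    def test_no_attrition_equals_exact_with_zero_variance(self):
        tree = eh.generate_yule_tree(6, seed=32)
        et = build(tree, 0.0)
        X = frozenset(tree.tips())
        tip = tree.tips()[0]
        mc = eh.partitioned_phi_mc(et, tip, X, eh.MonteCarloConfig(reps=100, seed=0))
        assert mc.value == pytest.approx(
            eh.partitioned_phi_exact(et, {tip}, X), abs=1e-12
        )
        assert mc.stderr <= 1e-12  # all replicates identical (float-mean noise only)

    def test_within_three_se_of_exact(self):
        tree = eh.make_ultrametric_and_date(eh.generate_yule_tree(6, seed=11), 10.0)
        et = build(tree, 0.1)
        X = frozenset(tree.tips())
        for tip in tree.tips():
            exact = eh.partitioned_phi_exact(et, {tip}, X)
            mc = eh.partitioned_phi_mc(
                et, tip, X, eh.MonteCarloConfig(reps=10_000, seed=1)
            )
            assert abs(mc.value - exact) <= 3.0 * mc.stderr

    def test_seeded_determinism(self):
        tree = eh.generate_yule_tree(6, seed=33)
        et = build(tree, 0.2)
        X = frozenset(tree.tips())
        cfg = eh.MonteCarloConfig(reps=2000, seed=7)
        a = eh.partitioned_phi_mc(et, "t1", X, cfg)
        b = eh.partitioned_phi_mc(et, "t1", X, cfg)
        assert a.value == b.value and a.stderr == b.stderr
        c = eh.partitioned_phi_mc(et, "t1", X, eh.MonteCarloConfig(reps=2000, seed=8))
        assert c.value != a.value
        assert abs(c.value - a.value) <= 3.0 * (a.stderr + c.stderr)

    def test_whole_tree_sampler_cross_check(self):
        tree = eh.generate_yule_tree(5, seed=34)
        et = build(tree, 0.3)
        X = frozenset(tree.tips())
        exact = eh.partitioned_phi_exact(et, {"t1"}, X)
        naive = partitioned_phi_mc_whole_tree(
            et, "t1", X, eh.MonteCarloConfig(reps=4000, seed=3)
        )
        assert abs(naive.value - exact) <= 3.0 * naive.stderr

    def test_focal_vertex_must_be_in_x(self, cherry):
        et = build(cherry, 0.2)
        with pytest.raises(ValueError):
            eh.partitioned_phi_mc(et, "a", {"b"}, eh.MonteCarloConfig(reps=10, seed=0))


class TestTheorem2Dichotomy:
    """PD can reproduce phi under attrition only on very simple shapes."""

    @staticmethod
    def _correspondence_residual(tree, rho):
        from evoheritage.phi import _spanning_edges

        et = build(tree, rho)
        tips = tree.tips()
        subsets = [
            frozenset(c)
            for r in range(1, len(tips) + 1)
            for c in itertools.combinations(tips, r)
        ]
        edges = tree.edges()
        A = np.array(
            [[1.0 if e in _spanning_edges(tree, X) else 0.0 for e in edges] for X in subsets]
        )
        b = np.array([eh.phi(et, X) for X in subsets])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        return float(np.linalg.norm(A @ sol - b))

    def test_cherry_with_stem_has_pd_correspondence(self, cherry):
        assert self._correspondence_residual(cherry, 0.5) <= 1e-10

    def test_caterpillar_with_stem_has_none(self, caterpillar_stem):
        # the stem is ancestral to three tips, so no edge re-scaling exists
        assert self._correspondence_residual(caterpillar_stem, 0.5) > 1e-3


class TestLivingFossilness:
    def test_star_tips_score_equally(self, star4):
        win = eh.AccumulationWindow(1.0, 3.0)  # the stem only
        scores = dict(eh.living_fossil_ranking(star4, win, rho=0.01))
        values = list(scores.values())
        assert max(values) - min(values) <= 1e-10
        # each tip gets a quarter of the stem's surviving standardized alpha;
        # the survival factor is P(at least one pendant edge retains the unit)
        cond = eh.StandardConditions(rho=0.01)
        stem_alpha = eh.targeted_edge_alpha(cond, (1.0, 3.0), win)
        p_any = 1.0 - (1.0 - eh.edge_beta(cond, 1.0)) ** 4
        expected = math.log10(stem_alpha * p_any / eh.standardized_unit(cond) / 4)
        assert values[0] == pytest.approx(expected, abs=1e-9)

    def test_lone_sister_tip_scores_highest(self, imbalanced_dated):
        win = eh.AccumulationWindow(3.0, 5.0)  # the ancient stem period
        ranking = eh.living_fossil_ranking(imbalanced_dated, win, rho=0.01)
        assert ranking[0][0] == "a"
        assert ranking[0][1] > ranking[1][1]

    def test_zero_attrition_full_window_reduces_to_ed_ranking(self, imbalanced_dated):
        lf = eh.living_fossil_ranking(imbalanced_dated, eh.AccumulationWindow(), rho=0.0)
        ed = ed_ranking(imbalanced_dated)
        assert [t for t, _ in lf] == [t for t, _ in ed]

    def test_zero_share_reported_as_minus_inf(self, imbalanced_dated):
        # a window entirely above the tree leaves nothing to partition
        win = eh.AccumulationWindow(1000.0, 2000.0)
        score = eh.living_fossilness(
            imbalanced_dated, "a", frozenset(imbalanced_dated.tips()), win, rho=0.01
        )
        assert score == -math.inf
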