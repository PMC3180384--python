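"""Chronogram parsing, validation, branching times, scaling, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladediv import (
    BranchingTimes,
    Chronogram,
    SimConfig,
    TreeSample,
    branching_times,
    gamma_statistic,
    parse_newick,
    prune_random,
    scale_to_unit_depth,
    simulate_tree,
    write_newick,
)
from cladediv.treeio import (
    NewickFormatError,
    NotBinaryError,
    UltrametricityError,
    UnsupportedSizeError,
)


class TestParse:
    def test_three_tip_read_off(self, three_tip_newick):
        tree = parse_newick(three_tip_newick)
        assert isinstance(tree, Chronogram)
        assert tree.n_tips == 3
        assert tree.depth == pytest.approx(2.0)
        assert tree.tip_labels == ["A", "B", "C"]
        assert np.allclose(tree.node_ages(), [2.0, 1.0])

    def test_non_ultrametric_rejected(self):
        with pytest.raises(UltrametricityError, match="deviation"):
            parse_newick("((A:1,B:2):1,C:2);")

    def test_polytomy_rejected(self):
        with pytest.raises(NotBinaryError, match="3 children"):
            parse_newick("(A:1,B:1,C:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(NewickFormatError):
            parse_newick("((A:1,B),C:2);")

    def test_tiny_tip_jitter_snapped(self):
        tree = parse_newick("((A:1.0000001,B:1):1,C:2);")
        assert tree.depth == pytest.approx(2.0000001)
        # after snapping all tips are exactly contemporaneous
        bt = branching_times(tree)
        assert np.sum(bt.intervals) == pytest.approx(tree.depth, abs=1e-12)

    def test_two_tips_unsupported(self):
        with pytest.raises(UnsupportedSizeError):
            parse_newick("(A:1,B:1);")

    def test_multiline_gives_sample(self, tmp_path):
        path = tmp_path / "two.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:2,B:2):1,C:3);\n")
        sample = parse_newick(path)
        assert isinstance(sample, TreeSample)
        assert len(sample) == 2
        assert sample.trees[1].depth == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_roundtrip_preserves_lengths(self, seed, tmp_path):
        tree = simulate_tree(SimConfig(model="yule", n_tips=25, lam=2.0, seed=seed))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = parse_newick(path)
        assert back.tip_labels == tree.tip_labels
        # identical topology ...
        import dendropy
        from dendropy.calculate import treecompare

        tns = dendropy.TaxonNamespace()
        t0 = dendropy.Tree.get(
            data=tree.as_newick(), schema="newick", taxon_namespace=tns
        )
        t1 = dendropy.Tree.get(
            data=back.as_newick(), schema="newick", taxon_namespace=tns
        )
        assert treecompare.symmetric_difference(t0, t1) == 0
        # ... and branch lengths preserved to 1e-9 relative (up to the
        # tip-snapping correction, which is bounded by the accumulated
        # 10-digit rounding, i.e. ~1e-9 of the tree depth in absolute terms)
        e0 = sorted(e.length for e in t0.preorder_edge_iter() if e.length)
        e1 = sorted(e.length for e in t1.preorder_edge_iter() if e.length)
        np.testing.assert_allclose(e1, e0, rtol=1e-9, atol=1e-8 * tree.depth)


class TestBranchingTimes:
    def test_hand_example(self, three_tip_newick):
        bt = branching_times(parse_newick(three_tip_newick))
        assert bt.n == 3
        np.testing.assert_allclose(bt.ages, [2.0, 1.0])
        np.testing.assert_allclose(bt.intervals, [1.0, 1.0])
        assert bt.total == pytest.approx(2 * 1 + 3 * 1)

    def test_tied_ages_zero_interval(self):
        tree = parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        bt = branching_times(tree)
        np.testing.assert_allclose(sorted(bt.ages), [0.5, 0.5, 1.0])
        np.testing.assert_allclose(bt.intervals, [0.5, 0.0, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_conservation(self, seed):
        tree = simulate_tree(SimConfig(model="yule", n_tips=30, lam=1.0, seed=seed))
        bt = branching_times(tree)
        assert np.sum(bt.intervals) == pytest.approx(tree.depth, abs=1e-9)
        assert np.all(np.diff(bt.cumulative) >= 0)

    def test_from_intervals_roundtrip(self):
        bt = BranchingTimes.from_intervals([0.3, 0.2, 0.5])
        np.testing.assert_allclose(bt.intervals, [0.3, 0.2, 0.5])
        np.testing.assert_allclose(bt.ages, [1.0, 0.7, 0.5])


class TestScale:
    def test_division(self, three_tip_newick):
        scaled = scale_to_unit_depth(parse_newick(three_tip_newick))
        assert scaled.depth == pytest.approx(1.0, abs=1e-12)
        assert scaled.as_newick().strip() == "((A:0.5,B:0.5):0.5,C:1);"

    def test_identity_on_unit_tree(self):
        tree = parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        again = scale_to_unit_depth(tree)
        np.testing.assert_allclose(again.node_ages(), tree.node_ages())

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_gamma_scale_invariant(self, seed):
        tree = simulate_tree(SimConfig(model="yule", n_tips=15, lam=3.0, seed=seed))
        g0 = gamma_statistic(branching_times(tree)).gamma
        g1 = gamma_statistic(branching_times(scale_to_unit_depth(tree))).gamma
        assert g1 == pytest.approx(g0, abs=1e-9)


class TestPrune:
    def test_keep_all_is_noop(self, yule_tree):
        pruned = prune_random(yule_tree, yule_tree.n_tips, seed=0)
        assert pruned is yule_tree

    def test_keep_three_minimal(self, yule_tree):
        pruned = prune_random(yule_tree, 3, seed=0)
        assert pruned.n_tips == 3
        assert set(pruned.tip_labels) <= set(yule_tree.tip_labels)
        # depth equals the retained tips' MRCA age, never more than original
        assert pruned.depth <= yule_tree.depth + 1e-12

    def test_seed_reproducible(self, yule_tree):
        a = prune_random(yule_tree, 10, seed=5).as_newick()
        b = prune_random(yule_tree, 10, seed=5).as_newick()
        c = prune_random(yule_tree, 10, seed=6).as_newick()
        assert a == b
        assert a != c

    def test_keep_exceeds_tips(self, yule_tree):
        with pytest.raises(ValueError, match="exceeds"):
            prune_random(yule_tree, yule_tree.n_tips + 1, seed=0)

    def test_pruning_biases_gamma_negative(self):
        """Random taxon removal shifts gamma left relative to full trees."""
        full, pruned = [], []
        for i in range(400):
            rng = np.random.default_rng(np.random.SeedSequence((17, i)))
            tree = simulate_tree(SimConfig(model="yule", n_tips=30, lam=1.0), rng)
            full.append(gamma_statistic(branching_times(tree)).gamma)
            sub = prune_random(tree, 15, rng=rng)
            pruned.append(gamma_statistic(branching_times(sub)).gamma)
        assert np.mean(pruned) < np.mean(full) - 0.2
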