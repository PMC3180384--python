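"""Tree simulators: distributional checks, determinism, fixture suite."""

import numpy as np
import pytest
from scipy import stats

from cladediv import (
    BranchingTimes,
    SimConfig,
    branching_times,
    full_clade_size,
    gamma_statistic,
    make_fixture_suite,
    parse_newick,
    simulate_pruned_null,
    simulate_tree,
    yule_intervals,
)
from cladediv.simulate import DEFAULT_FIXTURE_SPECS, InfeasibleParametersError


class TestPureBirth:
    def test_seed_determinism(self):
        cfg = SimConfig(model="yule", n_tips=5, lam=1.0, seed=42)
        assert simulate_tree(cfg).as_newick() == simulate_tree(cfg).as_newick()

    def test_total_lineage_time_mean(self):
        """T = sum k*g_k is a sum of n-1 unit-mean exponentials."""
        rng = np.random.default_rng(1)
        T = [
            BranchingTimes.from_intervals(yule_intervals(50, 1.0, rng)).total
            for _ in range(2000)
        ]
        assert np.mean(T) == pytest.approx(49.0, abs=1.0)

    def test_ddl_large_K_matches_yule(self):
        """With K -> inf the diversity-dependent intervals are pure birth."""
        g2_yule, g2_ddl = [], []
        for i in range(2000):
            rng = np.random.default_rng(np.random.SeedSequence((3, i)))
            ty = simulate_tree(SimConfig(model="yule", n_tips=8, lam=1.0), rng)
            td = simulate_tree(
                SimConfig(model="ddl", n_tips=8, r1=1.0, K=1e9),
                np.random.default_rng(np.random.SeedSequence((4, i))),
            )
            g2_yule.append(branching_times(ty).intervals[0])
            g2_ddl.append(branching_times(td).intervals[0])
        assert stats.ks_2samp(g2_yule, g2_ddl).pvalue > 0.01

    def test_gamma_invariant_to_rate(self):
        """The gamma null does not depend on the speciation rate."""
        out = {}
        for lam in (0.5, 5.0):
            rng = np.random.default_rng(12)
            out[lam] = [
                gamma_statistic(
                    BranchingTimes.from_intervals(yule_intervals(40, lam, rng))
                ).gamma
                for _ in range(1000)
            ]
        assert stats.ks_2samp(out[0.5], out[5.0]).pvalue > 0.01

    def test_gamma_null_five_percent_quantile(self):
        """Complete pure-birth gamma: 5% point near the asymptotic -1.645."""
        rng = np.random.default_rng(99)
        gs = [
            gamma_statistic(
                BranchingTimes.from_intervals(yule_intervals(500, 1.0, rng))
            ).gamma
            for _ in range(8000)
        ]
        assert np.quantile(gs, 0.05) == pytest.approx(-1.645, abs=0.06)

    def test_ddl_slowdown_gives_negative_gamma(self):
        gs = []
        for i in range(200):
            rng = np.random.default_rng(np.random.SeedSequence((5, i)))
            tree = simulate_tree(
                SimConfig(model="ddl", n_tips=38, r1=5.0, K=40.0), rng
            )
            gs.append(gamma_statistic(branching_times(tree)).gamma)
        assert np.mean(gs) < -1.0

    def test_ddl_infeasible_K(self):
        with pytest.raises(InfeasibleParametersError, match="K"):
            simulate_tree(SimConfig(model="ddl", n_tips=10, r1=1.0, K=9.0, seed=0))

    def test_yule2_shift_slows_branching(self):
        """Late-rate drop concentrates nodes early (negative gamma)."""
        gs = []
        for i in range(200):
            rng = np.random.default_rng(np.random.SeedSequence((6, i)))
            tree = simulate_tree(
                SimConfig(model="yule2", n_tips=30, r1=8.0, r2=0.5, st=0.4), rng
            )
            gs.append(gamma_statistic(branching_times(tree)).gamma)
        assert np.mean(gs) < -1.0


class TestBirthDeath:
    def test_mu_zero_matches_yule(self):
        """bd with no extinction is distributionally the yule simulator."""
        root_bd, root_y = [], []
        for i in range(1000):
            tb = simulate_tree(
                SimConfig(model="bd", n_tips=10, lam=1.0, mu=0.0),
                np.random.default_rng(np.random.SeedSequence((7, i))),
            )
            ty = simulate_tree(
                SimConfig(model="yule", n_tips=10, lam=1.0),
                np.random.default_rng(np.random.SeedSequence((8, i))),
            )
            root_bd.append(tb.depth)
            root_y.append(ty.depth)
        assert stats.ks_2samp(root_bd, root_y).pvalue > 0.01

    def test_with_extinction_valid_tree(self):
        tree = simulate_tree(SimConfig(model="bd", n_tips=12, lam=2.0, mu=1.0, seed=3))
        assert tree.n_tips == 12
        bt = branching_times(tree)
        assert np.sum(bt.intervals) == pytest.approx(tree.depth, abs=1e-9)


class TestFullCladeSize:
    @pytest.mark.parametrize(
        "known,expect", [(13, 14), (10, 11), (20, 22), (55, 61), (29, 32)]
    )
    def test_ten_percent_rule(self, known, expect):
        assert full_clade_size(known) == expect

    def test_zero_extra_identity(self):
        assert full_clade_size(17, extra_fraction=0.0) == 17

    def test_bad_input(self):
        with pytest.raises(ValueError):
            full_clade_size(2)


class TestPrunedNull:
    def test_postconditions(self):
        sample = simulate_pruned_null(n_sampled=6, n_full=9, reps=25, seed=0)
        assert len(sample) == 25
        for tree in sample:
            assert tree.n_tips == 6
            assert tree.depth == pytest.approx(1.0, abs=1e-9)

    def test_no_pruning_when_complete(self):
        sample = simulate_pruned_null(n_sampled=8, n_full=8, reps=5, seed=0)
        assert all(t.n_tips == 8 for t in sample)

    def test_replicates_order_independent(self):
        a = simulate_pruned_null(5, 8, reps=10, seed=1)
        b = simulate_pruned_null(5, 8, reps=3, seed=1)
        for ta, tb in zip(a.trees[:3], b.trees):
            assert ta.as_newick() == tb.as_newick()


class TestFixtureSuite:
    def test_default_suite(self, tmp_path):
        paths = make_fixture_suite(tmp_path / "fx", seed=0)
        assert len(paths) == 9
        by_name = {s.name: s for s in DEFAULT_FIXTURE_SPECS}
        for path in paths:
            tree = parse_newick(path)
            assert tree.n_tips == by_name[path.stem].n_sampled
            assert tree.depth == pytest.approx(1.0, abs=1e-9)
        meta = (tmp_path / "fx" / "fixtures.tsv").read_text().splitlines()
        assert len(meta) == 10  # header + nine clades

    def test_byte_identical_for_seed(self, tmp_path):
        p1 = make_fixture_suite(tmp_path / "a", seed=4)
        p2 = make_fixture_suite(tmp_path / "b", seed=4)
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_sampled_cannot_exceed_known(self):
        from cladediv import FixtureSpec

        with pytest.raises(ValueError):
            FixtureSpec(
                name="bad", n_sampled=12, known_total=10, age=1.0,
                generating_model=SimConfig(model="yule", n_tips=12),
            )
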