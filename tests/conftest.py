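import numpy as np
import pytest

from cladediv import SimConfig, branching_times, scale_to_unit_depth, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_tip_newick():
    return "((A:1,B:1):1,C:2);"


@pytest.fixture
def yule_tree():
    """One seeded constant-rate tree, unit depth, 20 tips."""
    tree = simulate_tree(SimConfig(model="yule", n_tips=20, lam=1.0, seed=7))
    return scale_to_unit_depth(tree)


@pytest.fixture
def ddl_tree():
    """One seeded diversity-dependent tree with a strong slowdown."""
    tree = simulate_tree(
        SimConfig(model="ddl", n_tips=38, r1=5.0, K=40.0, seed=11)
    )
    return scale_to_unit_depth(tree)


@pytest.fixture
def yule_bt(yule_tree):
    return branching_times(yule_tree)


@pytest.fixture
def ddl_bt(ddl_tree):
    return branching_times(ddl_tree)


def random_trees(n_trees, n_tips, seed, model="yule", **kw):
    """Helper: a list of unit-depth simulated trees."""
    out = []
    for i in range(n_trees):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        cfg = SimConfig(model=model, n_tips=n_tips, **kw)
        out.append(scale_to_unit_depth(simulate_tree(cfg, rng)))
    return out
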