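"""Forward simulation of reconstructed trees under diversification models.

This is the synthetic-data generator for the whole battery: it produces the
null trees behind the MCCR test and the bootstrap ΔAIC p-value, and a
nine-clade fixture suite emulating the New Caledonian datasets the battery
was designed around (sampled/known species counts and crown ages as reported
for those clades; the topologies and branch lengths are synthetic).

Models
------
``yule``
    Constant-rate pure birth: while k lineages exist the waiting time to the
    next speciation is Exponential(k*lambda).
``bd``
    Constant-rate birth-death, simulated forward with extinction and
    conditioned on reaching ``n_tips`` surviving lineages by acceptance
    sampling, then pruned of extinct lineages.
``yule2``
    Pure birth with a single rate shift (r1 then r2).
``ddl`` / ``ddx``
    Diversity-dependent speciation, linear ``r1*(1 - k/K)`` or exponential
    ``r1*k**(-x)`` in the standing lineage count k.

For all pure-birth family models, the reconstructed tree is cut at the
instant the (n_tips+1)-th speciation event would begin, so the final
interval g_n is a full Exponential(n*lambda_n) draw; each new lineage
attaches to a uniformly chosen extant lineage and tips are labelled
``t1..tn`` in birth order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .treeio import Chronogram, TreeSample, prune_random, scale_to_unit_depth

__all__ = [
    "SimConfig",
    "FixtureSpec",
    "InfeasibleParametersError",
    "simulate_tree",
    "yule_intervals",
    "simulate_pruned_null",
    "full_clade_size",
    "make_fixture_suite",
    "DEFAULT_FIXTURE_SPECS",
]

_MAX_BD_ATTEMPTS = 100_000


class InfeasibleParametersError(ValueError):
    """Simulation parameters give a non-positive speciation rate."""


@dataclass
class SimConfig:
    """Parameters of one simulated reconstructed tree.

    Only the parameters of ``model`` are consulted:
    yule: ``lam``; bd: ``lam, mu``; yule2: ``r1, r2, st`` (``st`` is the
    shift time measured forward from the crown); ddl: ``r1, K``;
    ddx: ``r1, x``.
    """

    model: str
    n_tips: int
    lam: float = 1.0
    mu: float = 0.0
    r1: float = 1.0
    r2: float = 1.0
    K: float = 0.0
    x: float = 0.0
    st: float = 0.0
    seed: int | None = None


def _rates_per_k(config: SimConfig) -> np.ndarray | None:
    """Per-lineage rate lambda_k for k = 2..n, or None for time-dependent."""
    n = config.n_tips
    ks = np.arange(2, n + 1)
    if config.model == "yule":
        if config.lam <= 0:
            raise InfeasibleParametersError("yule needs lam > 0")
        return np.full(n - 1, config.lam)
    if config.model == "ddl":
        rates = config.r1 * (1.0 - ks / config.K)
        if config.r1 <= 0 or np.any(rates <= 0):
            raise InfeasibleParametersError(
                f"ddl with r1={config.r1}, K={config.K} gives a non-positive "
                f"rate before reaching {n} lineages (need K > n_tips)"
            )
        return rates
    if config.model == "ddx":
        if config.r1 <= 0:
            raise InfeasibleParametersError("ddx needs r1 > 0")
        return config.r1 * ks ** (-config.x)
    return None


def yule_intervals(
    n_tips: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Internode durations g_2..g_n of one pure-birth tree.

    Equivalent in distribution to the intervals of :func:`simulate_tree`
    with the ``yule`` model; useful when only branching times are needed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if lam <= 0:
        raise InfeasibleParametersError("yule needs lam > 0")
    ks = np.arange(2, n_tips + 1)
    return rng.exponential(1.0 / (ks * lam))


def _build_from_events(
    n: int, event_times: np.ndarray, depth: float, rng: np.random.Generator
) -> Chronogram:
    """Assemble a tree from split times (forward from the crown at 0)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    counter = [0]

    def new_leaf(birth):
        counter[0] += 1
        node = dendropy.Node()
        node._birth = birth  # forward time of this lineage's origin
        node._order = counter[0]
        return node

    extant = []
    for _ in range(2):
        child = new_leaf(0.0)
        root.add_child(child)
        extant.append(child)
    for t in event_times:
        i = int(rng.integers(len(extant)))
        parent = extant[i]
        parent.edge.length = t - parent._birth
        c1, c2 = new_leaf(t), new_leaf(t)
        parent.add_child(c1)
        parent.add_child(c2)
        extant[i] = c1
        extant.append(c2)
    for leaf in extant:
        leaf.edge.length = depth - leaf._birth
    for rank, leaf in enumerate(sorted(extant, key=lambda nd: nd._order), 1):
        leaf.taxon = tns.new_taxon(label=f"t{rank}")
    return Chronogram(tree)


def _simulate_purebirth(config: SimConfig, rng: np.random.Generator) -> Chronogram:
    n = config.n_tips
    if config.model == "yule2":
        if config.r1 <= 0 or config.r2 <= 0:
            raise InfeasibleParametersError("yule2 needs r1, r2 > 0")
        if config.st <= 0:
            raise InfeasibleParametersError("yule2 needs st > 0")
        # Piecewise-constant hazard: integrate an Exp(1) draw through the
        # rate change at forward time st.
        g = np.empty(n - 1)
        t = 0.0
        for j, k in enumerate(range(2, n + 1)):
            e = rng.exponential()
            if t >= config.st:
                w = e / (k * config.r2)
            else:
                budget = k * config.r1 * (config.st - t)
                if e <= budget:
                    w = e / (k * config.r1)
                else:
                    w = (config.st - t) + (e - budget) / (k * config.r2)
            g[j] = w
            t += w
    else:
        rates = _rates_per_k(config)
        ks = np.arange(2, n + 1)
        g = rng.exponential(1.0 / (ks * rates))
    times = np.cumsum(g)
    return _build_from_events(n, times[:-1], float(times[-1]), rng)


def _simulate_bd(config: SimConfig, rng: np.random.Generator) -> Chronogram:
    n, lam, mu = config.n_tips, config.lam, config.mu
    if lam <= 0 or mu < 0:
        raise InfeasibleParametersError("bd needs lam > 0 and mu >= 0")
    if mu == 0.0:
        return _simulate_purebirth(
            SimConfig(model="yule", n_tips=n, lam=lam), rng
        )
    p_birth = lam / (lam + mu)
    for _ in range(_MAX_BD_ATTEMPTS):
        # events: list of (time, parent_index) splits; lineages tracked by
        # index with birth/death times, resolved into a tree on success.
        birth = [0.0, 0.0]
        death = [math.inf, math.inf]
        parent = [-1, -1]
        extant = [0, 1]
        t = 0.0
        ok = False
        while True:
            k = len(extant)
            if k == 0:
                break
            t += rng.exponential(1.0 / (k * (lam + mu)))
            is_birth = rng.random() < p_birth
            if is_birth and k == n:
                ok = True  # cut just before the (n+1)-th lineage arises
                break
            i = extant[int(rng.integers(k))]
            if is_birth:
                for _ in range(2):
                    birth.append(t)
                    death.append(math.inf)
                    parent.append(i)
                    extant.append(len(birth) - 1)
                death[i] = t
                extant.remove(i)
            else:
                death[i] = t
                extant.remove(i)
        if ok:
            return _resolve_bd_tree(birth, death, parent, extant, t)
    raise RuntimeError(
        f"bd simulation failed to reach {n} survivors in "
        f"{_MAX_BD_ATTEMPTS} attempts"
    )


def _resolve_bd_tree(birth, death, parent, survivors, depth) -> Chronogram:
    """Reconstructed tree on the surviving lineages of a bd realisation."""
    m = len(birth)
    children: list[list[int]] = [[] for _ in range(m)]
    for i in range(m):
        if parent[i] >= 0:
            children[parent[i]].append(i)
    surviving = set(survivors)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    # Post-order over lineage indices (iterative; roots are 0 and 1).
    order: list[int] = []
    stack = [0, 1]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    results: dict[int, tuple | None] = {}
    label_rank = {idx: r for r, idx in enumerate(sorted(surviving), 1)}
    for i in reversed(order):
        end = death[i] if death[i] < math.inf else depth
        elen = end - birth[i]
        if not children[i]:
            if i in surviving:
                node = dendropy.Node(
                    taxon=tns.new_taxon(label=f"t{label_rank[i]}")
                )
                results[i] = (node, elen)
            else:
                results[i] = None
        else:
            kept = [results[c] for c in children[i] if results[c]]
            if not kept:
                results[i] = None
            elif len(kept) == 1:
                child, clen = kept[0]
                results[i] = (child, clen + elen)
            else:
                node = dendropy.Node()
                for child, clen in kept:
                    child.edge.length = clen
                    node.add_child(child)
                results[i] = (node, elen)
    tops = [results[i] for i in (0, 1) if results[i]]
    if len(tops) == 2:
        root = dendropy.Node()
        for child, clen in tops:
            child.edge.length = clen
            root.add_child(child)
    else:  # one crown lineage died out entirely
        root, _ = tops[0]
    root.edge.length = None
    tree.seed_node = root
    return Chronogram(tree)


def simulate_tree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Chronogram:
    """Simulate one reconstructed tree with exactly ``config.n_tips`` tips."""
    if config.n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.model == "bd":
        return _simulate_bd(config, rng)
    if config.model in ("yule", "yule2", "ddl", "ddx"):
        return _simulate_purebirth(config, rng)
    raise ValueError(f"unknown model {config.model!r}")


def _replicate_rng(seed: int, i: int) -> np.random.Generator:
    """Counter-based per-replicate stream: reproducible, order-independent."""
    return np.random.default_rng(np.random.SeedSequence((seed, i)))


def full_clade_size(known_total: int, extra_fraction: float = 0.10) -> int:
    """Hypothetical full clade size: known species + assumed unknown extras.

    Rounds to the nearest integer, half away from zero (13 -> 14 at the
    default 10% extra).
    """
    if known_total < 3:
        raise ValueError("known_total must be >= 3")
    if extra_fraction < 0:
        raise ValueError("extra_fraction must be >= 0")
    return int(math.floor(known_total * (1.0 + extra_fraction) + 0.5))


def simulate_pruned_null(
    n_sampled: int,
    n_full: int,
    reps: int,
    seed: int,
    lam: float = 1.0,
) -> TreeSample:
    """Pure-birth trees of ``n_full`` tips pruned to ``n_sampled``, unit depth.

    The null sample behind the MCCR test: each replicate simulates a
    complete constant-rate tree at the hypothetical full clade size, prunes
    tips uniformly at random down to the sampled count, and rescales to
    depth 1.
    """
    if not 3 <= n_sampled <= n_full:
        raise ValueError("need 3 <= n_sampled <= n_full")
    trees = []
    for i in range(reps):
        rng = _replicate_rng(seed, i)
        tree = simulate_tree(SimConfig(model="yule", n_tips=n_full, lam=lam), rng)
        if n_sampled < n_full:
            tree = prune_random(tree, n_sampled, rng=rng)
        trees.append(scale_to_unit_depth(tree))
    return TreeSample(trees=trees, label=f"yule {n_full}->{n_sampled} null")


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """A synthetic stand-in for one clade's chronogram.

    ``n_sampled``/``known_total``/``age`` mirror the published per-clade
    numbers; ``generating_model`` controls the (synthetic) tree shape.
    """

    name: str
    n_sampled: int
    known_total: int
    age: float
    generating_model: SimConfig

    def __post_init__(self):
        if self.n_sampled > self.known_total:
            raise ValueError("n_sampled cannot exceed known_total")


def _ddl_spec(name, n_sampled, known_total, age, r1=5.0):
    K = max(full_clade_size(known_total), n_sampled + 1)
    return FixtureSpec(
        name=name,
        n_sampled=n_sampled,
        known_total=known_total,
        age=age,
        generating_model=SimConfig(model="ddl", n_tips=n_sampled, r1=r1, K=K),
    )


#: Nine clade-like fixtures (sampled/known/age as published); all generated
#: under diversity-dependent slowdown except Helicopha (constant-rate).
DEFAULT_FIXTURE_SPECS: list[FixtureSpec] = [
    _ddl_spec("Niemeyera", 47, 55, 32.4),
    _ddl_spec("Scincidae", 42, 47, 38.05),
    _ddl_spec("Troglosironidae", 11, 13, 49.0),
    _ddl_spec("Papuadytes", 15, 18, 9.0),
    _ddl_spec("Gracilipsodes", 10, 10, 14.4),
    FixtureSpec(
        name="Helicopha",
        n_sampled=19,
        known_total=20,
        age=8.2,
        generating_model=SimConfig(model="yule", n_tips=19, lam=1.0),
    ),
    _ddl_spec("Xanthochorema", 10, 10, 11.9),
    _ddl_spec("Hydropsychinae", 28, 29, 28.2),
    _ddl_spec("Agmina", 75, 80, 21.9),
]


def make_fixture_suite(
    out_dir,
    specs: list[FixtureSpec] | None = None,
    seed: int = 0,
) -> list[Path]:
    """Write one unit-depth Newick file per spec plus a metadata table.

    Returns the list of written tree paths.  Byte-identical for a fixed
    seed.
    """
    if specs is None:
        specs = DEFAULT_FIXTURE_SPECS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    meta_lines = ["name\tn_sampled\tknown_total\tage_ma\tmodel\tparams"]
    for i, spec in enumerate(specs):
        rng = _replicate_rng(seed, i)
        tree = scale_to_unit_depth(simulate_tree(spec.generating_model, rng))
        path = out_dir / f"{spec.name}.nwk"
        path.write_text(tree.as_newick())
        paths.append(path)
        cfg = spec.generating_model
        if cfg.model == "yule":
            params = f"lam={cfg.lam:g}"
        elif cfg.model == "ddl":
            params = f"r1={cfg.r1:g},K={cfg.K:g}"
        else:
            params = ""
        meta_lines.append(
            f"{spec.name}\t{spec.n_sampled}\t{spec.known_total}"
            f"\t{spec.age:g}\t{cfg.model}\t{params}"
        )
    (out_dir / "fixtures.tsv").write_text("\n".join(meta_lines) + "\n")
    return paths
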