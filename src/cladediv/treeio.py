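"""Chronogram I/O, validation, and branching-time extraction.

A chronogram is a rooted, binary, ultrametric tree whose branch lengths are
proportional to time.  Everything downstream (the gamma statistic, the
diversification likelihoods) consumes only the vector of node ages, so this
module is responsible for getting from Newick text to a validated
:class:`BranchingTimes` object, and for the two tree transforms the analyses
need: rescaling to unit root depth and random pruning of tips.

Conventions
-----------
* Node "age" is time before present; tips sit at age 0 and the crown (root)
  at age equal to the tree depth.
* Ultrametricity is checked to a relative tolerance of ``1e-6``; smaller
  deviations (rounding noise from numerical ultrametrization) are removed by
  snapping terminal branches so tips are exactly contemporaneous.  Larger
  deviations raise :class:`UltrametricityError`.
* An explicit root edge in the input is discarded; inner-node labels are
  ignored; the tree is always interpreted as rooted.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "ChronogramError",
    "NewickFormatError",
    "NotBinaryError",
    "UltrametricityError",
    "DegenerateTreeError",
    "UnsupportedSizeError",
    "Chronogram",
    "TreeSample",
    "BranchingTimes",
    "parse_newick",
    "write_newick",
    "branching_times",
    "scale_to_unit_depth",
    "prune_random",
]

#: Relative tolerance on root-to-tip path spread before a tree is rejected.
ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Base class for chronogram validation and format errors."""


class NewickFormatError(ChronogramError):
    """Malformed Newick, or branch lengths missing from non-root edges."""


class NotBinaryError(ChronogramError):
    """The tree contains a polytomy (or an unresolved internal node)."""


class UltrametricityError(ChronogramError):
    """Root-to-tip path lengths disagree beyond tolerance."""


class DegenerateTreeError(ChronogramError):
    """A tree with zero depth (all branch lengths zero)."""


class UnsupportedSizeError(ChronogramError):
    """Fewer tips than the statistic in question is defined for."""


class Chronogram:
    """A validated rooted binary ultrametric tree.

    Wraps a :class:`dendropy.Tree`.  Construction validates structure
    (binary, branch lengths present and non-negative, >= 3 tips),
    ultrametricity, and snaps tips to exactly age 0.

    Parameters
    ----------
    tree:
        A rooted dendropy tree.  The instance takes ownership; callers that
        want to keep the original should pass a clone.
    """

    __slots__ = ("_tree", "_depth", "_tip_labels")

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        tree = self._tree
        root = tree.seed_node
        # An explicit root edge carries no information here.
        root.edge.length = None

        depths: dict = {root: 0.0}
        tip_nodes = []
        for node in tree.preorder_node_iter():
            if node is not root:
                elen = node.edge.length
                if elen is None:
                    raise NewickFormatError(
                        "branch length missing on a non-root edge"
                    )
                if elen < 0:
                    raise NewickFormatError(
                        f"negative branch length {elen!r}"
                    )
                depths[node] = depths[node.parent_node] + elen
            children = node.child_nodes()
            if children:
                if len(children) != 2:
                    label = node.taxon.label if node.taxon else (
                        node.label or f"<node at depth {depths[node]:.6g}>"
                    )
                    raise NotBinaryError(
                        f"internal node {label} has {len(children)} children"
                        " (binary tree required)"
                    )
            else:
                tip_nodes.append(node)

        if len(tip_nodes) < 3:
            raise UnsupportedSizeError(
                f"chronogram needs >= 3 tips, got {len(tip_nodes)}"
            )

        tip_depths = np.array([depths[t] for t in tip_nodes])
        depth = float(tip_depths.max())
        if depth <= 0.0:
            raise DegenerateTreeError("tree has zero depth")
        max_dev = float(np.max(np.abs(tip_depths - depth)))
        if max_dev > ULTRAMETRIC_RTOL * depth:
            raise UltrametricityError(
                f"tree is not ultrametric: max root-to-tip deviation "
                f"{max_dev:.6g} exceeds tolerance {ULTRAMETRIC_RTOL * depth:.6g} "
                f"(relative {max_dev / depth:.3g})"
            )
        # Snap tips to exactly age 0 by adjusting terminal edges.
        for node, d in zip(tip_nodes, tip_depths):
            if d != depth:
                node.edge.length += depth - d

        labels = []
        for t in tip_nodes:
            labels.append(t.taxon.label if t.taxon else (t.label or ""))
        if len(set(labels)) != len(labels):
            raise NewickFormatError("duplicate tip labels")
        self._tip_labels = labels
        self._depth = depth

    # -- basic accessors ------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the order encountered in the tree."""
        return list(self._tip_labels)

    @property
    def depth(self) -> float:
        """Root-to-tip distance (crown age) in the tree's time units."""
        return self._depth

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def clone(self) -> "Chronogram":
        return Chronogram(self._tree.clone(depth=1))

    def node_ages(self) -> np.ndarray:
        """Ages (time before present) of internal nodes, sorted descending."""
        root = self._tree.seed_node
        depths = {root: 0.0}
        ages = []
        for node in self._tree.preorder_node_iter():
            if node is not root:
                depths[node] = depths[node.parent_node] + node.edge.length
            if node.child_nodes():
                ages.append(self._depth - depths[node])
        ages = np.sort(np.array(ages))[::-1]
        # The root sits exactly at the depth by construction.
        ages[0] = self._depth
        return np.maximum(ages, 0.0)

    # -- serialization --------------------------------------------------

    def as_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram n_tips={self.n_tips} depth={self.depth:.6g}>"


@dataclass
class TreeSample:
    """An ordered collection of chronograms (e.g. posterior draws)."""

    trees: list[Chronogram]
    label: str = ""

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


@dataclass(frozen=True)
class BranchingTimes:
    """Node ages and internode intervals of an n-tip chronogram.

    Attributes
    ----------
    n:
        Tip count.
    ages:
        The n-1 node ages before present, descending; ``ages[0]`` is the
        crown age (tree depth).
    """

    n: int
    ages: np.ndarray = field(repr=False)

    @classmethod
    def from_ages(cls, ages) -> "BranchingTimes":
        ages = np.sort(np.asarray(ages, dtype=float))[::-1]
        if len(ages) < 2:
            raise UnsupportedSizeError(
                "need >= 2 node ages (>= 3 tips) for branching times"
            )
        if ages[-1] < 0:
            raise ChronogramError("negative node age")
        return cls(n=len(ages) + 1, ages=ages)

    @classmethod
    def from_intervals(cls, intervals) -> "BranchingTimes":
        """Build from internode durations ``g_k`` for k = 2..n."""
        g = np.asarray(intervals, dtype=float)
        if np.any(g < 0):
            raise ChronogramError("negative internode interval")
        ages = np.cumsum(g[::-1])[::-1]
        return cls.from_ages(ages)

    @property
    def depth(self) -> float:
        return float(self.ages[0])

    @property
    def intervals(self) -> np.ndarray:
        """Durations g_k during which exactly k lineages exist, k = 2..n."""
        return -np.diff(np.append(self.ages, 0.0))

    @property
    def cumulative(self) -> np.ndarray:
        """T_i = sum_{k=2..i} k*g_k for i = 2..n."""
        ks = np.arange(2, self.n + 1)
        return np.cumsum(ks * self.intervals)

    @property
    def total(self) -> float:
        """T = T_n, the total lineage-time from the crown to the present."""
        return float(self.cumulative[-1])


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------


def _is_path(source) -> bool:
    if isinstance(source, (os.PathLike,)):
        return True
    return isinstance(source, str) and ";" not in source and "(" not in source


def parse_newick(source) -> Chronogram | TreeSample:
    """Parse Newick text or a file into a chronogram or a tree sample.

    One tree per line; a file with several trees yields a
    :class:`TreeSample`, a single tree a :class:`Chronogram`.
    """
    if _is_path(source):
        with open(source) as fh:
            data = fh.read()
    else:
        data = str(source)
    try:
        tree_list = dendropy.TreeList.get(
            data=data,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickFormatError(f"could not parse Newick input: {exc}") from exc
    if len(tree_list) == 0:
        raise NewickFormatError("no trees found in input")
    chronos = [Chronogram(t) for t in tree_list]
    if len(chronos) == 1:
        return chronos[0]
    return TreeSample(trees=chronos)


def write_newick(obj: Chronogram | TreeSample, path) -> None:
    """Write a chronogram (or one tree per line for a sample) to Newick."""
    trees = obj.trees if isinstance(obj, TreeSample) else [obj]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick())


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def branching_times(tree: Chronogram) -> BranchingTimes:
    """Extract node ages / internode intervals from a chronogram."""
    if tree.n_tips < 3:
        raise UnsupportedSizeError("branching times need >= 3 tips")
    return BranchingTimes.from_ages(tree.node_ages())


def scale_to_unit_depth(tree: Chronogram) -> Chronogram:
    """Rescale all branch lengths so the root-to-tip depth equals 1."""
    depth = tree.depth
    if depth <= 0:
        raise DegenerateTreeError("cannot rescale a zero-depth tree")
    new = tree.dendropy_tree.clone(depth=1)
    for edge in new.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Chronogram(new)


def _induced_subtree(tree: Chronogram, keep_labels: set[str]) -> Chronogram:
    """Subtree induced by a set of tip labels, unary nodes suppressed."""
    src = tree.dendropy_tree
    tns = dendropy.TaxonNamespace()
    new_tree = dendropy.Tree(taxon_namespace=tns)
    # results[node] = (new_node, pending_edge_length) or None
    results: dict = {}
    for node in src.postorder_node_iter():
        elen = node.edge.length if node.edge.length is not None else 0.0
        if not node.child_nodes():
            label = node.taxon.label if node.taxon else node.label
            if label in keep_labels:
                nn = dendropy.Node(taxon=tns.new_taxon(label=label))
                results[node] = (nn, elen)
            else:
                results[node] = None
        else:
            kept = [results[c] for c in node.child_nodes() if results[c]]
            if not kept:
                results[node] = None
            elif len(kept) == 1:
                child, child_len = kept[0]
                results[node] = (child, child_len + elen)
            else:
                nn = dendropy.Node()
                for child, child_len in kept:
                    child.edge.length = child_len
                    nn.add_child(child)
                results[node] = (nn, elen)
    top = results[src.seed_node]
    if top is None:  # pragma: no cover - guarded by keep >= 3
        raise ChronogramError("no tips retained")
    new_root, _ = top
    new_root.edge.length = None
    new_tree.seed_node = new_root
    return Chronogram(new_tree)


def prune_random(
    tree: Chronogram,
    keep: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Chronogram:
    """Randomly retain ``keep`` tips, mimicking incomplete taxon sampling.

    The surviving subtree is ultrametric with depth equal to the age of the
    most recent common ancestor of the retained tips.
    """
    n = tree.n_tips
    if keep > n:
        raise ValueError(f"keep={keep} exceeds tip count {n}")
    if keep < 3:
        raise ValueError("must keep at least 3 tips")
    if keep == n:
        return tree
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    idx = rng.choice(n, size=keep, replace=False)
    return _induced_subtree(tree, {labels[i] for i in idx})
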