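"""Rooted time-calibrated trees: Newick I/O, ages, pruning, subsampling.

The tree is stored as flat parent-pointer arrays, which is what the pruning
likelihood and the mapping samplers want.  Newick parsing and writing are
delegated to :mod:`dendropy`; this module only converts to and from the
array representation.

Branch lengths are interpreted as time in Myr throughout the package.
Polytomies are accepted and treated as hard multifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "NewickError",
    "read_newick",
    "write_newick",
    "node_ages",
    "drop_tips",
    "subsample_one_per_group",
]

#: default relative tolerance for ultrametricity checks; published megatrees
#: carry rounding noise of this order.
DEFAULT_ULTRAMETRIC_TOL = 1e-3


class NewickError(ValueError):
    """Raised for malformed Newick input (parse errors, duplicate tips,
    missing branch lengths)."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted phylogeny with branch lengths, as parent-pointer arrays.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node id of node ``i``; ``-1`` at the root.
    edge_length
        Length (Myr) of the edge above each node; ``0.0`` at the root.
    labels
        Per-node label; every tip must carry a unique label, internal labels
        are optional and preserved on round-trip.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: tuple

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        edge = np.asarray(self.edge_length, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "edge_length", edge)
        if parent.shape != edge.shape or len(self.labels) != parent.size:
            raise ValueError("parent, edge_length and labels must have equal length")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any(edge[np.flatnonzero(parent >= 0)] < 0):
            raise ValueError("negative branch length")
        tips = [self.labels[i] for i in self.tip_indices]
        if any(lab is None for lab in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise NewickError("duplicate tip labels")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @cached_property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @cached_property
    def children(self) -> tuple:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return tuple(tuple(k) for k in kids)

    @cached_property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero([len(k) == 0 for k in self.children])

    @cached_property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    @cached_property
    def preorder(self) -> np.ndarray:
        """Node ids, every parent before its children."""
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return np.asarray(order, dtype=np.int64)

    @cached_property
    def postorder(self) -> np.ndarray:
        """Node ids, every child before its parent."""
        return self.preorder[::-1].copy()

    @cached_property
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.edge_length[v]
        return d

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (tree height, Myr)."""
        return float(self.depths[self.tip_indices].max())

    def tip_index(self, label: str) -> int:
        try:
            return int(self.tip_indices[self.tip_labels.index(label)])
        except ValueError:
            raise KeyError(f"no tip labelled {label!r}") from None

    @cached_property
    def total_length(self) -> float:
        """Sum of all branch lengths (Myr)."""
        mask = self.parent >= 0
        return float(self.edge_length[mask].sum())

    def tip_distance_matrix(self) -> np.ndarray:
        """Pairwise patristic distances between tips, in ``tip_labels`` order."""
        n = self.n_tips
        # descendant tip sets by postorder accumulation
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        tip_pos = {int(t): j for j, t in enumerate(self.tip_indices)}
        dist = np.zeros((n, n))
        for v in self.postorder:
            if not self.children[v]:
                below[v] = [v]
                continue
            kids = self.children[v]
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    for ta in below[kids[a_i]]:
                        for tb in below[kids[b_i]]:
                            d = (
                                self.depths[ta]
                                + self.depths[tb]
                                - 2.0 * self.depths[v]
                            )
                            ia, ib = tip_pos[ta], tip_pos[tb]
                            dist[ia, ib] = dist[ib, ia] = d
            below[v] = [t for k in kids for t in below[k]]
        return dist

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        edge = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    name = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                    raise NewickError(f"missing branch length above node {name!r}")
                edge[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
        return cls(parent, edge, tuple(labels))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                dnodes[p].add_child(dnodes[v])
                dnodes[v].edge.length = float(self.edge_length[v])
            if not self.children[v]:
                dnodes[v].taxon = taxa.new_taxon(self.labels[v])
            elif self.labels[v] is not None:
                dnodes[v].label = self.labels[v]
        tree.seed_node = dnodes[self.root]
        return tree


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths must be present on every non-root edge; duplicate tip
    labels and malformed syntax raise :class:`NewickError` naming the
    offending token.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; round-trips topology and lengths through
    :func:`read_newick` up to quoting and numeric formatting."""
    return (
        tree.to_dendropy().as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
    ).strip() + "\n"


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree))


# ---------------------------------------------------------------------------
# Ages and pruning


def node_ages(tree: PhyloTree, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> np.ndarray:
    """Ages before present for every node of an ultrametric tree.

    Parameters
    ----------
    tol
        Relative tolerance on root-to-tip path spread: the tree is accepted
        if ``max depth - min depth <= tol * depth``.

    Returns
    -------
    ages
        Array over nodes; tips are clamped to exactly 0, the root equals the
        tree depth.
    """
    depths = tree.depths
    tip_d = depths[tree.tip_indices]
    height = float(tip_d.max())
    spread = float(tip_d.max() - tip_d.min())
    if height > 0 and spread > tol * height:
        raise ValueError(
            f"tree is not ultrametric within tol={tol}: "
            f"max root-to-tip deviation {spread:.6g} on depth {height:.6g}"
        )
    ages = height - depths
    ages[tree.tip_indices] = 0.0
    return ages


def drop_tips(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    """Remove the named tips, suppressing degree-2 nodes (lengths summed).

    Pairwise path lengths among the remaining tips are preserved exactly.
    If the old root is left with a single child, that child becomes the new
    root and the dangling root edge is discarded.
    """
    drop = set(labels)
    tipset = set(tree.tip_labels)
    unknown = drop - tipset
    if unknown:
        raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
    if not (tipset - drop):
        raise ValueError("cannot drop all tips")

    keep = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[i] not in drop:
            keep[i] = True
    for v in tree.postorder:
        if tree.children[v] and any(keep[c] for c in tree.children[v]):
            keep[v] = True

    # rebuild top-down, suppressing kept nodes with a single kept child
    new_parent: list[int] = []
    new_edge: list[float] = []
    new_labels: list = []

    # if the root itself becomes unary, descend to the first multifurcation/tip
    v = tree.root
    while True:
        kids = [c for c in tree.children[v] if keep[c]]
        if len(kids) == 1:
            v = kids[0]
        else:
            break

    stack = [(v, -1, 0.0)]  # node, new parent id, carried length
    while stack:
        v, parent_new, carried = stack.pop()
        kids = [c for c in tree.children[v] if keep[c]]
        length = carried + (tree.edge_length[v] if tree.parent[v] >= 0 else 0.0)
        if len(kids) == 1 and tree.children[v]:
            # unifurcation: splice out, accumulate length
            stack.append((kids[0], parent_new, length))
            continue
        my_id = len(new_parent)
        new_parent.append(parent_new)
        new_edge.append(length if parent_new >= 0 else 0.0)
        new_labels.append(tree.labels[v])
        for c in reversed(kids):
            stack.append((c, my_id, 0.0))
    # the new root carries no edge
    new_edge[0] = 0.0
    return PhyloTree(
        np.asarray(new_parent), np.asarray(new_edge), tuple(new_labels)
    )


def subsample_one_per_group(
    tree: PhyloTree, group_of: Mapping[str, str], seed: int
) -> PhyloTree:
    """Retain one randomly chosen tip per group (e.g. one species per genus).

    The choice is a deterministic function of ``(tree, group_of, seed)``:
    groups and members are visited in sorted order and drawn with
    ``numpy.random.default_rng(seed)``.
    """
    if tree.n_tips == 0:
        raise ValueError("empty tree")
    missing = [t for t in tree.tip_labels if t not in group_of]
    if missing:
        raise KeyError(f"tips without a group: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for t in tree.tip_labels:
        groups.setdefault(group_of[t], []).append(t)
    rng = np.random.default_rng(seed)
    keep = set()
    for g in sorted(groups):
        members = sorted(groups[g])
        keep.add(members[rng.integers(len(members))])
    to_drop = [t for t in tree.tip_labels if t not in keep]
    return drop_tips(tree, to_drop) if to_drop else tree
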