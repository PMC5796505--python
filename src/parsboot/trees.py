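"""Unrooted phylogenetic trees and the moves used by the parsimony search.

Nodes are integers: ids below ``len(taxa)`` are leaves (the id doubles as the
taxon index), larger ids are internal nodes of degree three (degree >= 3 for
multifurcating consensus output).  Trees are topological only — parsimony has
no branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .costs import CostModel
from .patterns import PatternAlignment
from .scoring import score_tree, tree_total


class NewickError(ValueError):
    pass


class PhyloTree:
    """Mutable unrooted tree over a fixed taxon set."""

    __slots__ = ("taxa", "adj", "_next_id", "support")

    def __init__(self, taxa, adj=None, support=None):
        self.taxa = tuple(taxa)
        self.adj: dict[int, list[int]] = adj if adj is not None else {}
        self._next_id = max(self.adj, default=len(self.taxa) - 1) + 1
        # optional per-split support percentages keyed by split bitmask
        self.support: dict[int, float] = support if support is not None else {}

    # -- construction -----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def new_internal(self) -> int:
        node = self._next_id
        self._next_id += 1
        self.adj[node] = []
        return node

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, []).append(v)
        self.adj.setdefault(v, []).append(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def copy(self) -> "PhyloTree":
        t = PhyloTree.__new__(PhyloTree)
        t.taxa = self.taxa
        t.adj = {u: list(nbrs) for u, nbrs in self.adj.items()}
        t._next_id = self._next_id
        t.support = dict(self.support)
        return t

    @classmethod
    def star3(cls, taxa, leaf_ids) -> "PhyloTree":
        """The unique unrooted tree on three leaves."""
        t = cls(taxa)
        center = t.new_internal()
        for leaf in leaf_ids:
            t.add_edge(leaf, center)
        return t

    # -- inspection -------------------------------------------------------

    def is_leaf(self, u: int) -> bool:
        return u < self.n_taxa

    def leaves(self) -> list[int]:
        return sorted(u for u in self.adj if u < self.n_taxa)

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self):
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    yield (u, v)

    def internal_edges(self):
        return [
            (u, v) for u, v in self.edges() if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def validate(self, allow_polytomy: bool = False, full: bool = True) -> None:
        """Raise if the tree is not a valid (binary, by default) unrooted tree."""
        if full and set(self.leaves()) != set(range(self.n_taxa)):
            raise ValueError("leaf set does not match taxa")
        n_edges = sum(len(v) for v in self.adj.values()) // 2
        if n_edges != len(self.adj) - 1:
            raise ValueError("edge count wrong for a tree")
        # connectivity
        seen = set()
        stack = [next(iter(self.adj))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.adj[u])
        if seen != set(self.adj):
            raise ValueError("tree not connected")
        for u, nbrs in self.adj.items():
            if len(set(nbrs)) != len(nbrs):
                raise ValueError("parallel edges")
            if self.is_leaf(u):
                if len(nbrs) != 1:
                    raise ValueError(f"leaf {u} has degree {len(nbrs)}")
            elif len(nbrs) < 3 or (not allow_polytomy and len(nbrs) != 3):
                raise ValueError(f"internal node {u} has degree {len(nbrs)}")

    # -- splits -----------------------------------------------------------

    def splits(self) -> frozenset[int]:
        """Nontrivial splits as bitmasks of the side not containing taxon 0."""
        return frozenset(self._edge_splits().values())

    def _edge_splits(self) -> dict[tuple[int, int], int]:
        """Map each internal-split edge (parent, child) to its bitmask."""
        n = self.n_taxa
        root = min(u for u in self.adj if u < n)
        parent = {root: -1}
        order = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    stack.append(v)
        below: dict[int, int] = {}
        result: dict[tuple[int, int], int] = {}
        for u in reversed(order):
            if u < n:
                below[u] = 1 << u
            else:
                below[u] = 0
                for v in self.adj[u]:
                    if v != parent[u]:
                        below[u] |= below[v]
        for u in order:
            if u == root:
                continue
            mask = below[u]
            size = mask.bit_count()
            if 2 <= size <= n - 2:
                result[(parent[u], u)] = mask
        return result

    def topology_key(self) -> frozenset[int]:
        return self.splits()


# -- Newick I/O -----------------------------------------------------------


def parse_newick(text: str, taxa=None) -> PhyloTree:
    """Parse a Newick string (polytomies allowed); internal node labels are
    interpreted as split support values and kept on the returned tree."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"invalid newick: {exc}") from exc
    dleaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else lf.label for lf in dleaves]
    if any(lab is None for lab in labels):
        raise NewickError("unlabelled leaf")
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate leaf labels")
    if taxa is not None:
        if set(labels) != set(taxa):
            raise NewickError("leaf labels do not match the expected taxa")
        taxa = tuple(taxa)
    else:
        taxa = tuple(labels)
    index = {lab: i for i, lab in enumerate(taxa)}

    tree = PhyloTree(taxa)
    n = len(taxa)
    full = (1 << n) - 1
    labelled: list[tuple[str, int]] = []  # (label, subtree leaf mask)

    def build(dnode) -> tuple[int, int]:
        if dnode.is_leaf():
            leaf = index[dnode.taxon.label if dnode.taxon else dnode.label]
            return leaf, 1 << leaf
        node = tree.new_internal()
        mask = 0
        for child in dnode.child_nodes():
            cnode, cmask = build(child)
            tree.add_edge(node, cnode)
            mask |= cmask
        if dnode.label is not None:
            labelled.append((dnode.label, mask))
        return node, mask

    root, _ = build(dtree.seed_node)
    # suppress a degree-2 root left by rooted newick input
    if not tree.is_leaf(root) and tree.degree(root) == 2:
        a, b = tree.adj[root]
        tree.remove_edge(root, a)
        tree.remove_edge(root, b)
        del tree.adj[root]
        tree.add_edge(a, b)
    tree.validate(allow_polytomy=True)
    # attach numeric internal labels as split supports, canonicalized to the
    # side of the split that excludes taxon 0
    for label, mask in labelled:
        if mask & 1:
            mask = full & ~mask
        if not 2 <= mask.bit_count() <= n - 2:
            continue
        try:
            tree.support[mask] = float(label)
        except ValueError:
            pass
    return tree


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def write_newick(tree: PhyloTree, with_support: bool = False, support=None) -> str:
    """Write topology-only Newick; optional integer support values become
    internal node labels (phylip style, rounded half-up)."""
    sup = support if support is not None else tree.support
    node_split = (
        {child: mask for (parent, child), mask in tree._edge_splits().items()}
        if with_support
        else {}
    )

    ref = min(u for u in tree.adj if u < tree.n_taxa)
    root = tree.adj[ref][0]
    if tree.is_leaf(root):  # degenerate 2-node tree; not produced in practice
        return f"({tree.taxa[ref]},{tree.taxa[root]});"

    def emit(u: int, parent: int) -> str:
        if tree.is_leaf(u):
            return tree.taxa[u]
        inner = ",".join(emit(v, u) for v in tree.adj[u] if v != parent)
        label = ""
        if with_support and u in node_split and node_split[u] in sup:
            label = str(_round_half_up(sup[node_split[u]]))
        return f"({inner}){label}"

    return f"({','.join(emit(v, root) for v in tree.adj[root])});"


# -- SPR ------------------------------------------------------------------


@dataclass(frozen=True)
class SprMove:
    """Prune the subtree on ``sub``'s side of edge (sub, attach) and regraft
    it onto ``target``; ``radius`` counts the nodes between the two branches."""

    sub: int
    attach: int
    others: tuple[int, int]  # the attach node's two remaining neighbors
    target: tuple[int, int]
    radius: int


def spr_neighbors(tree: PhyloTree, radius: int | None = None):
    """Yield every distinct SPR move within the radius; none of them
    recreates the current topology."""
    if radius is not None and radius < 1:
        raise ValueError("radius must be >= 1")
    for v in sorted(u for u in tree.adj if not tree.is_leaf(u)):
        for a in sorted(tree.adj[v]):
            p, q = (x for x in tree.adj[v] if x != a)
            # BFS distances from the attachment node within the remaining tree
            dist = {v: 0}
            frontier = [v]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in tree.adj[u]:
                        if w == a and u == v:
                            continue  # do not enter the pruned subtree
                        if w not in dist:
                            dist[w] = dist[u] + 1
                            nxt.append(w)
                frontier = nxt
            for c in sorted(dist):
                for d in tree.adj[c]:
                    if c >= d or c == v or d == v or d not in dist:
                        continue
                    r = min(dist[c], dist[d])
                    if radius is None or r <= radius:
                        yield SprMove(sub=a, attach=v, others=(p, q), target=(c, d), radius=r)


def apply_spr(tree: PhyloTree, move: SprMove) -> None:
    p, q = move.others
    c, d = move.target
    v = move.attach
    tree.remove_edge(v, p)
    tree.remove_edge(v, q)
    tree.add_edge(p, q)
    tree.remove_edge(c, d)
    tree.add_edge(v, c)
    tree.add_edge(v, d)


def undo_spr(tree: PhyloTree, move: SprMove) -> None:
    p, q = move.others
    c, d = move.target
    v = move.attach
    tree.remove_edge(v, c)
    tree.remove_edge(v, d)
    tree.add_edge(c, d)
    tree.remove_edge(p, q)
    tree.add_edge(v, p)
    tree.add_edge(v, q)


# -- NNI ------------------------------------------------------------------


def nni_alternatives(tree: PhyloTree, edge: tuple[int, int]):
    """The two rearrangements across an internal edge, as (u, a, v, b) swaps."""
    u, v = edge
    if tree.is_leaf(u) or tree.is_leaf(v):
        raise ValueError("NNI requires an internal edge")
    a = [x for x in tree.adj[u] if x != v][1]
    bs = [x for x in tree.adj[v] if x != u]
    return [(u, a, v, b) for b in bs]


def apply_nni(tree: PhyloTree, swap) -> None:
    u, a, v, b = swap
    tree.remove_edge(u, a)
    tree.remove_edge(v, b)
    tree.add_edge(u, b)
    tree.add_edge(v, a)


def random_nni_perturb(tree: PhyloTree, fraction: float, rng) -> PhyloTree:
    """Apply one random NNI at ceil(fraction * #internal-edges) distinct
    internal edges of a copy of the tree."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    t = tree.copy()
    t.support = {}
    inner = t.internal_edges()
    count = math.ceil(fraction * len(inner))
    chosen = [inner[i] for i in rng.choice(len(inner), size=count, replace=False)]
    for i, (u, v) in enumerate(chosen):
        swap = nni_alternatives(t, (u, v))[int(rng.integers(2))]
        apply_nni(t, swap)
        # an NNI at (u, v) relocates edges (u, a) -> (v, a) and (v, b) -> (u, b);
        # remap any still-pending selected edge so each chosen branch is used once
        _, a, _, b = swap
        for j in range(i + 1, len(chosen)):
            if set(chosen[j]) == {u, a}:
                chosen[j] = (v, a)
            elif set(chosen[j]) == {v, b}:
                chosen[j] = (u, b)
    return t


# -- search primitives ----------------------------------------------------


def attach_leaf(tree: PhyloTree, leaf: int, edge: tuple[int, int]) -> int:
    """Subdivide ``edge`` with a new node and hang ``leaf`` from it."""
    u, v = edge
    w = tree.new_internal()
    tree.remove_edge(u, v)
    tree.add_edge(u, w)
    tree.add_edge(w, v)
    tree.add_edge(w, leaf)
    return w


def detach_leaf(tree: PhyloTree, leaf: int, w: int, edge: tuple[int, int]) -> None:
    u, v = edge
    tree.remove_edge(w, leaf)
    tree.remove_edge(u, w)
    tree.remove_edge(w, v)
    del tree.adj[w]
    del tree.adj[leaf]
    tree.add_edge(u, v)


def random_stepwise_addition(pa: PatternAlignment, cm: CostModel, rng) -> PhyloTree:
    """Insert taxa in random order, each on the edge minimizing the parsimony
    score of the extended tree; ties are broken uniformly at random."""
    n = pa.n_taxa
    if n < 4:
        raise ValueError("need at least 4 taxa")
    order = rng.permutation(n)
    tree = PhyloTree.star3(pa.taxa, [int(x) for x in order[:3]])
    for leaf in order[3:]:
        leaf = int(leaf)
        best_edges: list[tuple[int, int]] = []
        best = None
        for edge in list(tree.edges()):
            w = attach_leaf(tree, leaf, edge)
            total = tree_total(tree, pa, cm)
            detach_leaf(tree, leaf, w, edge)
            if best is None or total < best:
                best = total
                best_edges = [edge]
            elif total == best:
                best_edges.append(edge)
        attach_leaf(tree, leaf, best_edges[int(rng.integers(len(best_edges)))])
    return tree


def hill_climb_spr(
    t0: PhyloTree,
    pa: PatternAlignment,
    cm: CostModel,
    radius: int | None = 6,
    weights: np.ndarray | None = None,
    on_accept=None,
) -> PhyloTree:
    """Best-improvement SPR hill climbing.

    Repeatedly applies the strictly-improving move (within the radius) with
    the lowest resulting score until none exists.  ``on_accept`` is called
    with ``(tree_copy, PatternScoreVector)`` after every accepted move and,
    if no move was ever accepted, once with the (locally optimal) start tree.
    """
    tree = t0.copy()
    tree.support = {}
    current = tree_total(tree, pa, cm, weights)
    accepted_any = False
    while True:
        best_move = None
        best_total = current
        for move in spr_neighbors(tree, radius):
            apply_spr(tree, move)
            total = tree_total(tree, pa, cm, weights)
            undo_spr(tree, move)
            if total < best_total:
                best_total = total
                best_move = move
        if best_move is None:
            break
        apply_spr(tree, best_move)
        current = best_total
        accepted_any = True
        if on_accept is not None:
            on_accept(tree.copy(), score_tree(tree, pa, cm, weights))
    if not accepted_any and on_accept is not None:
        on_accept(tree.copy(), score_tree(tree, pa, cm, weights))
    return tree
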