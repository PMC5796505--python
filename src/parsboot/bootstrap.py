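"""Bootstrap replicates as resampled pattern-weight vectors, per-replicate
best-tree tracking by rescoring precomputed pattern scores, the refinement
pass, and support summarization (mapping onto the best tree and majority-rule
consensus)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .costs import CostModel
from .patterns import PatternAlignment
from .scoring import (
    ABORTED,
    PatternScoreVector,
    ReplicateOrder,
    reps_score,
    reps_score_with_abort,
    tree_total,
)
from .trees import PhyloTree, hill_climb_spr


@dataclass
class BootstrapReplicate:
    """One pseudo-replicate: resampled weights and its best tree so far."""

    index: int
    weights: np.ndarray  # int64, sum == m
    best_tree: PhyloTree | None = None
    best_score: float = math.inf
    order: ReplicateOrder | None = field(default=None, repr=False)


def make_replicates(
    pa: PatternAlignment, B: int, rng, order: ReplicateOrder | None = None
) -> list[BootstrapReplicate]:
    """Draw B weight vectors: multinomial resampling of the m informative
    site slots with per-pattern probabilities d_i / m."""
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    probs = pa.weights / pa.m
    weight_matrix = rng.multinomial(pa.m, probs, size=B).astype(np.int64)
    return [
        BootstrapReplicate(index=b, weights=weight_matrix[b], order=order)
        for b in range(B)
    ]


def attach_order(reps: list[BootstrapReplicate], order: ReplicateOrder) -> None:
    for rep in reps:
        rep.order = order


def offer_tree(
    tree: PhyloTree,
    psv: PatternScoreVector,
    reps: list[BootstrapReplicate],
    bounds: np.ndarray,
    use_abort: bool = True,
) -> None:
    """Evaluate a search tree against every replicate; on strict improvement
    the replicate adopts (a shared frozen copy of) the tree.  Ties keep the
    incumbent, so the abort bound never changes any outcome."""
    shared_copy: PhyloTree | None = None
    for rep in reps:
        if use_abort and rep.order is not None:
            result = reps_score_with_abort(
                psv, rep.weights, rep.order, bounds, rep.best_score
            )
            if result is ABORTED:
                continue
            score = result
        else:
            score = reps_score(psv, rep.weights)
        if score < rep.best_score:
            if shared_copy is None:
                shared_copy = tree.copy()
            rep.best_tree = shared_copy
            rep.best_score = score


def refine(
    reps: list[BootstrapReplicate],
    pa: PatternAlignment,
    cm: CostModel,
    radius: int | None,
) -> None:
    """Hill-climb each replicate's best tree under that replicate's weights;
    keep the refined tree iff it scores strictly better.  Scores never worsen."""
    for rep in reps:
        if rep.best_tree is None:
            raise RuntimeError(
                f"replicate {rep.index} has no tree; the search offered none"
            )
        climbed = hill_climb_spr(rep.best_tree, pa, cm, radius, weights=rep.weights)
        score = tree_total(climbed, pa, cm, rep.weights)
        if score < rep.best_score:
            rep.best_tree = climbed
            rep.best_score = score


@dataclass
class SupportedTree:
    """A topology with per-split support percentages (keyed by split bitmask)."""

    tree: PhyloTree
    support: dict[int, float]

    def newick(self) -> str:
        return_tree = self.tree
        from .trees import write_newick

        return write_newick(return_tree, with_support=True, support=self.support)


def _split_counts(reps: list[BootstrapReplicate]):
    counts: dict[int, int] = {}
    for rep in reps:
        for split in rep.best_tree.splits():
            counts[split] = counts.get(split, 0) + 1
    return counts


def support_on_best_tree(
    best: PhyloTree, reps: list[BootstrapReplicate]
) -> SupportedTree:
    """Annotate each internal edge of the best tree with the percentage of
    replicate trees whose split set contains that edge's split."""
    counts = _split_counts(reps)
    B = len(reps)
    support = {
        split: 100.0 * counts.get(split, 0) / B for split in best.splits()
    }
    return SupportedTree(tree=best.copy(), support=support)


def majority_consensus(
    reps: list[BootstrapReplicate], threshold: float = 50.0
) -> SupportedTree:
    """Majority-rule consensus: every split in strictly more than
    ``threshold`` percent of replicate trees (threshold >= 50 guarantees the
    included splits are pairwise compatible).  Output may be multifurcating."""
    if threshold < 50:
        raise ValueError("threshold below 50 can select incompatible splits")
    counts = _split_counts(reps)
    B = len(reps)
    taxa = reps[0].best_tree.taxa
    n = len(taxa)
    included = {
        split: 100.0 * c / B for split, c in counts.items() if 100.0 * c / B > threshold
    }

    # build the rooted cluster tree of the laminar split family; splits are
    # bitmasks of the side not containing taxon 0, i.e. clusters w.r.t. taxon 0
    tree = PhyloTree(taxa)
    root = tree.new_internal()
    clusters = sorted(included, key=lambda s: -s.bit_count())
    node_of: dict[int, int] = {}
    parent_mask: dict[int, int] = {}
    full = ((1 << n) - 1) & ~1  # every taxon except taxon 0
    for mask in clusters:
        parent = root
        best_mask = full
        for other, node in node_of.items():
            if mask | other == other and other.bit_count() < best_mask.bit_count():
                parent = node
                best_mask = other
        node = tree.new_internal()
        node_of[mask] = node
        parent_mask[node] = mask
        tree.add_edge(parent, node)
    for leaf in range(n):
        bit = 1 << leaf
        parent = root
        best_size = n + 1
        for mask, node in node_of.items():
            if mask & bit and mask.bit_count() < best_size:
                parent = node
                best_size = mask.bit_count()
        tree.add_edge(leaf, parent)
    tree.validate(allow_polytomy=True)
    return SupportedTree(tree=tree, support=dict(included))
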