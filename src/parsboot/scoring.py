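"""Parsimony scoring: Fitch and Sankoff per-pattern scores, weighted totals,
bootstrap rescoring of precomputed pattern scores, and the early-abort bound.

The tree argument everywhere is duck-typed: anything with an ``adj`` mapping
node -> neighbor list, where node ids below the taxon count are leaves labelled
by taxon index.  Both scorers root internally at the smallest present leaf;
the returned scores are rooting-invariant for symmetric cost matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import CostModel
from .patterns import MISSING, PatternAlignment, states_for


class _Aborted:
    """Sentinel: the running lower bound exceeded the replicate's best score."""

    def __repr__(self) -> str:  # pragma: no cover
        return "ABORTED"


ABORTED = _Aborted()


def encode_column(column: str, alphabet_kind: str) -> np.ndarray:
    """Encode one alignment column (e.g. ``\"AACC\"``) as state codes."""
    states = states_for(alphabet_kind)
    return np.array(
        [states.index(c) if c in states else MISSING for c in column.upper()],
        dtype=np.int8,
    )


def _postorder(adj: dict, n_taxa: int):
    """(order, parent, root_leaf) for traversal rooted at the smallest leaf."""
    root = min(u for u in adj if u < n_taxa)
    parent = {root: -1}
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    order.reverse()
    return order, parent, root


def fitch_pattern_scores(tree, pa: PatternAlignment) -> np.ndarray:
    """Per-pattern change counts under uniform cost, all patterns at once."""
    adj = tree.adj
    masks = pa.fitch_masks()
    order, parent, root = _postorder(adj, pa.n_taxa)
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(pa.k, dtype=np.int64)
    for u in order:
        if u == root:
            continue
        if u < pa.n_taxa:
            sets[u] = masks[u]
            continue
        children = [v for v in adj[u] if v != parent[u]]
        acc = sets.pop(children[0])
        for c in children[1:]:
            other = sets.pop(c)
            inter = acc & other
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | other, inter)
        sets[u] = acc
    (top,) = [v for v in adj[root]]
    changes = changes + ((masks[root] & sets[top]) == 0)
    return changes


_INF = np.int64(1) << 40  # sentinel larger than any achievable weighted score


def sankoff_pattern_scores(tree, pa: PatternAlignment, cm: CostModel) -> np.ndarray:
    """Per-pattern minimal change costs for an arbitrary symmetric step matrix."""
    adj = tree.adj
    cost = cm.cost
    leaf_vecs = pa.sankoff_leaf_vectors(cm.key, cost, int(_INF))
    order, parent, root = _postorder(adj, pa.n_taxa)
    vecs: dict[int, np.ndarray] = {}
    for u in order:
        if u == root:
            continue
        if u < pa.n_taxa:
            vecs[u] = leaf_vecs[u]
            continue
        children = [v for v in adj[u] if v != parent[u]]
        acc = None
        for c in children:
            child = vecs.pop(c)
            # contribution[i, a] = min_b child[i, b] + cost[a, b]
            contrib = (child[:, None, :] + cost[None, :, :]).min(axis=2)
            acc = contrib if acc is None else acc + contrib
        vecs[u] = acc
    (top,) = [v for v in adj[root]]
    contrib = (vecs[top][:, None, :] + cost[None, :, :]).min(axis=2)
    return (leaf_vecs[root] + contrib).min(axis=1)


def pattern_scores(tree, pa: PatternAlignment, cm: CostModel) -> np.ndarray:
    if cm.is_uniform:
        return fitch_pattern_scores(tree, pa)
    return sankoff_pattern_scores(tree, pa, cm)


@dataclass(frozen=True)
class PatternScoreVector:
    """Per-pattern scores of one fixed tree plus their weighted total."""

    scores: np.ndarray
    total: int


def score_tree(
    tree, pa: PatternAlignment, cm: CostModel, weights: np.ndarray | None = None
) -> PatternScoreVector:
    """Score a tree whose leaf set equals the alignment taxa."""
    tree_leaves = {u for u in tree.adj if u < pa.n_taxa and len(tree.adj[u]) == 1}
    if tree_leaves != set(range(pa.n_taxa)):
        raise ValueError("tree leaf set does not match alignment taxa")
    scores = pattern_scores(tree, pa, cm)
    w = pa.weights if weights is None else np.asarray(weights, dtype=np.int64)
    return PatternScoreVector(scores=scores, total=int(scores @ w))


def tree_total(
    tree, pa: PatternAlignment, cm: CostModel, weights: np.ndarray | None = None
) -> int:
    """Weighted total only (hot path of the SPR scans; skips validation)."""
    scores = pattern_scores(tree, pa, cm)
    w = pa.weights if weights is None else weights
    return int(scores @ w)


def score_pattern_fitch(tree, column, alphabet_kind: str = "dna") -> int:
    """Fitch score of a single pattern given as a string or code vector."""
    pa = _single_pattern(column, alphabet_kind)
    return int(fitch_pattern_scores(tree, pa)[0])


def score_pattern_sankoff(tree, column, cm: CostModel) -> int:
    """Sankoff score of a single pattern given as a string or code vector."""
    kind = "dna" if len(cm.states) == 4 else "protein"
    pa = _single_pattern(column, kind)
    return int(sankoff_pattern_scores(tree, pa, cm)[0])


def _single_pattern(column, alphabet_kind: str) -> PatternAlignment:
    codes = (
        encode_column(column, alphabet_kind)
        if isinstance(column, str)
        else np.asarray(column, dtype=np.int8)
    )
    return PatternAlignment(
        taxa=tuple(f"_{i}" for i in range(len(codes))),
        matrix=codes[:, None],
        weights=np.ones(1, dtype=np.int64),
        alphabet_kind=alphabet_kind,
    )


@dataclass(frozen=True)
class ReplicateOrder:
    """Fixed pattern evaluation order: descending score on the first tree
    built in the initial search step, ties broken by ascending pattern index."""

    perm: np.ndarray

    @classmethod
    def from_first_tree_scores(cls, scores: np.ndarray) -> "ReplicateOrder":
        perm = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
        return cls(perm=perm)


def reps_score(psv: PatternScoreVector, weights: np.ndarray) -> int:
    """Exact bootstrap-replicate score: weighted sum of per-pattern scores."""
    w = np.asarray(weights)
    if w.shape != psv.scores.shape:
        raise ValueError("weight vector length mismatch")
    if (w < 0).any():
        raise ValueError("negative bootstrap weight")
    return int(psv.scores @ w.astype(np.int64))


def reps_score_with_abort(
    psv: PatternScoreVector,
    weights: np.ndarray,
    order: ReplicateOrder,
    bounds: np.ndarray,
    best: float,
):
    """Replicate score with early abort.

    Scans patterns in the fixed order accumulating exact scores for a prefix
    and per-pattern lower bounds for the suffix; returns :data:`ABORTED` as
    soon as the running value strictly exceeds ``best`` (the tree then cannot
    beat the replicate's incumbent), otherwise the exact score.
    """
    perm = order.perm
    if len(perm) != len(psv.scores):
        raise ValueError("replicate order does not cover all patterns")
    w = np.asarray(weights, dtype=np.int64)[perm]
    if (w < 0).any():
        raise ValueError("negative bootstrap weight")
    s = psv.scores[perm]
    b = np.asarray(bounds, dtype=np.int64)[perm]
    prefix = np.cumsum(s * w)
    bw = b * w
    # suffix[j] = sum_{i > j} bounds * w   (0 for the last position)
    suffix = np.concatenate([np.cumsum(bw[::-1])[-2::-1], [0]])
    running = prefix + suffix
    if best != np.inf and (running > best).any():
        return ABORTED
    return int(prefix[-1])
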