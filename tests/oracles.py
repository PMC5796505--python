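"""Independent oracles used by the test suite.

These deliberately avoid the package's scoring and move-enumeration code
paths: parsimony scores are obtained by exhaustive minimization over all
internal-node state assignments, and tree spaces by explicit enumeration of
every topology.
"""

from __future__ import annotations

import numpy as np

from parsboot import PhyloTree
from parsboot.patterns import PatternAlignment


def exhaustive_pattern_scores(tree: PhyloTree, pa: PatternAlignment, cost: np.ndarray) -> np.ndarray:
    """Per-pattern minimum total edge cost over every assignment of states to
    internal nodes.  A missing leaf contributes zero (it can copy its
    neighbor's state at zero cost because the diagonal is zero)."""
    adj = tree.adj
    n = pa.n_taxa
    s = cost.shape[0]
    internal = sorted(u for u in adj if u >= n)
    pos = {u: i for i, u in enumerate(internal)}
    grids = np.meshgrid(*([np.arange(s)] * len(internal)), indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1)  # (s^I, I)

    base = np.zeros(assign.shape[0], dtype=np.int64)
    leaf_terms = np.zeros((assign.shape[0], pa.k), dtype=np.int64)
    for u in sorted(adj):
        for v in adj[u]:
            if u >= v:
                continue
            if u >= n and v >= n:
                base += cost[assign[:, pos[u]], assign[:, pos[v]]]
            else:
                leaf, inner = (u, v) if u < n else (v, u)
                codes = pa.matrix[leaf]  # (k,)
                cols = np.where(codes >= 0, codes, 0).astype(np.int64)
                term = cost[assign[:, pos[inner]]][:, cols]
                term[:, codes < 0] = 0
                leaf_terms += term
    return (base[:, None] + leaf_terms).min(axis=0)


def exhaustive_score(tree: PhyloTree, column_codes: np.ndarray, cost: np.ndarray, alphabet_kind: str = "dna") -> int:
    """Single-pattern version of the exhaustive oracle."""
    pa = PatternAlignment(
        taxa=tuple(f"x{i}" for i in range(len(column_codes))),
        matrix=np.asarray(column_codes, dtype=np.int8)[:, None],
        weights=np.ones(1, dtype=np.int64),
        alphabet_kind=alphabet_kind,
    )
    return int(exhaustive_pattern_scores(tree, pa, cost)[0])


def all_topologies(n: int, taxa=None) -> list[PhyloTree]:
    """Every unrooted binary topology on n labelled leaves (3, 15, 105, ...)."""
    taxa = tuple(f"t{i + 1}" for i in range(n)) if taxa is None else tuple(taxa)
    trees = [PhyloTree.star3(taxa, [0, 1, 2])]
    for leaf in range(3, n):
        grown = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                w = t2.new_internal()
                t2.remove_edge(u, v)
                t2.add_edge(u, w)
                t2.add_edge(w, v)
                t2.add_edge(w, leaf)
                grown.append(t2)
        trees = grown
    return trees


def random_patterns(n_taxa: int, count: int, rng, n_states: int = 4, missing_prob: float = 0.15) -> np.ndarray:
    """Random state-code columns with occasional missing entries, (n_taxa, count)."""
    mat = rng.integers(0, n_states, size=(n_taxa, count)).astype(np.int8)
    mat[rng.random((n_taxa, count)) < missing_prob] = -1
    return mat
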