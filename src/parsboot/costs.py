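"""Step (cost) matrices and per-pattern parsimony lower bounds.

Supported matrices: uniform (all changes cost 1), DNA transition/transversion
(1/2), the amino-acid minimum-nucleotide-change matrix (repaired to satisfy
the triangle inequality), and user-supplied symmetric integer tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.sparse import csr_matrix

from .patterns import DNA_STATES, PROTEIN_STATES, states_for


class CostMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class CostModel:
    """Symmetric non-negative integer step matrix over an ordered alphabet."""

    states: str
    cost: np.ndarray  # int64, square
    is_uniform: bool = False
    _key: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.cost, dtype=np.int64)
        if c.shape != (len(self.states), len(self.states)):
            raise CostMatrixError("cost matrix shape does not match alphabet")
        if (c < 0).any():
            raise CostMatrixError("negative costs not allowed")
        if (np.diag(c) != 0).any():
            raise CostMatrixError("diagonal must be zero")
        if not (c == c.T).all():
            raise CostMatrixError("cost matrix must be symmetric")
        object.__setattr__(self, "cost", c)
        object.__setattr__(self, "_key", (self.states, c.tobytes()))

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def key(self) -> tuple:
        """Hashable identity used for per-alignment scoring caches."""
        return self._key

    @property
    def max_cost(self) -> int:
        return int(self.cost.max())

    def satisfies_triangle_inequality(self) -> bool:
        c = self.cost
        # cost[a,c] <= cost[a,b] + cost[b,c] for all a,b,c
        return bool((c <= (c[:, None, :] + c[None, :, :]).min(axis=1)).all())


def triangle_closure(cost: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path closure (Floyd-Warshall); never increases entries."""
    c = np.asarray(cost, dtype=np.int64).copy()
    n = c.shape[0]
    for k in range(n):
        np.minimum(c, c[:, k : k + 1] + c[k : k + 1, :], out=c)
    return c


def uniform_cost(alphabet_kind: str) -> CostModel:
    states = states_for(alphabet_kind)
    n = len(states)
    cost = np.ones((n, n), dtype=np.int64) - np.eye(n, dtype=np.int64)
    return CostModel(states=states, cost=cost, is_uniform=True)


def dna_titv_cost() -> CostModel:
    """Transitions (A<->G, C<->T) cost 1, transversions cost 2."""
    idx = {s: i for i, s in enumerate(DNA_STATES)}
    cost = np.full((4, 4), 2, dtype=np.int64)
    np.fill_diagonal(cost, 0)
    for a, b in (("A", "G"), ("C", "T")):
        cost[idx[a], idx[b]] = cost[idx[b], idx[a]] = 1
    return CostModel(states=DNA_STATES, cost=cost)


def protein_min_nt_cost() -> CostModel:
    """Minimum nucleotide changes between amino acids, triangle-repaired.

    Raw cost(a, b) is the minimum Hamming distance over codon pairs encoding
    a and b under the standard genetic code (stop codons excluded), then the
    matrix is closed under shortest paths so the triangle inequality holds.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    codons: dict[str, list[str]] = {aa: [] for aa in PROTEIN_STATES}
    for codon, aa in table.forward_table.items():
        codons[aa].append(codon)
    n = len(PROTEIN_STATES)
    raw = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(PROTEIN_STATES):
        for j, b in enumerate(PROTEIN_STATES):
            if j <= i:
                continue
            d = min(
                sum(x != y for x, y in zip(ca, cb))
                for ca in codons[a]
                for cb in codons[b]
            )
            raw[i, j] = raw[j, i] = d
    return CostModel(states=PROTEIN_STATES, cost=triangle_closure(raw))


def read_cost_matrix(path) -> CostModel:
    """Read a user step matrix: first line the alphabet, then a square table."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise CostMatrixError("empty cost matrix file")
    states = tokens[0].upper()
    n = len(states)
    if len(set(states)) != n:
        raise CostMatrixError("alphabet has repeated states")
    values = tokens[1:]
    if len(values) != n * n:
        raise CostMatrixError(f"expected {n * n} matrix entries, got {len(values)}")
    try:
        cost = np.array([int(v) for v in values], dtype=np.int64).reshape(n, n)
    except ValueError as exc:
        raise CostMatrixError(f"non-integer cost entry: {exc}") from exc
    cm = CostModel(states=states, cost=cost)
    if not cm.satisfies_triangle_inequality():
        raise CostMatrixError("cost matrix violates the triangle inequality")
    return cm


def pattern_lower_bound(pattern: np.ndarray, cm: CostModel) -> int:
    """Smallest score any tree can achieve on this pattern.

    Uniform costs: number of distinct observed states minus 1.  General
    costs: weight of a minimum spanning tree on the complete graph over the
    observed states with pairwise substitution costs as edge weights.
    Missing states are ignored; <=1 observed state bounds to 0.
    """
    observed = np.unique(pattern[pattern >= 0])
    if observed.size <= 1:
        return 0
    if cm.is_uniform:
        return int(observed.size - 1)
    sub = cm.cost[np.ix_(observed, observed)]
    # shift weights by +1 so zero-cost edges are not dropped by the sparse MST
    shifted = sub + 1 - np.eye(observed.size, dtype=np.int64)
    mst = minimum_spanning_tree(csr_matrix(shifted))
    return int(round(mst.sum())) - (observed.size - 1)


def all_pattern_lower_bounds(pa, cm: CostModel) -> np.ndarray:
    return np.array(
        [pattern_lower_bound(pa.pattern(i), cm) for i in range(pa.k)], dtype=np.int64
    )
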