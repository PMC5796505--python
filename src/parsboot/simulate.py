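"""Seeded synthetic data: random unrooted topologies and alignments evolved
along them under a symmetric per-site substitution process.  Used by the test
suite and the ``simulate`` CLI subcommand so nothing needs downloading."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import Alignment, states_for
from .trees import PhyloTree


@dataclass(frozen=True)
class SimSpec:
    n_taxa: int
    sites: int
    alphabet_kind: str = "dna"
    sub_prob: float = 0.1  # per-site substitution probability per edge
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.sites < 1:
            raise ValueError("need at least 1 site")
        if not 0 < self.sub_prob < 1:
            raise ValueError("substitution probability must be in (0, 1)")


def default_taxa(n: int) -> tuple[str, ...]:
    return tuple(f"t{i + 1}" for i in range(n))


def random_tree(n: int, rng, taxa=None) -> PhyloTree:
    """Uniform random unrooted binary topology by sequential attachment of
    each new leaf to a uniformly chosen edge."""
    if n < 4:
        raise ValueError("need at least 4 taxa")
    taxa = default_taxa(n) if taxa is None else tuple(taxa)
    tree = PhyloTree.star3(taxa, [0, 1, 2])
    for leaf in range(3, n):
        edges = list(tree.edges())
        u, v = edges[int(rng.integers(len(edges)))]
        w = tree.new_internal()
        tree.remove_edge(u, v)
        tree.add_edge(u, w)
        tree.add_edge(w, v)
        tree.add_edge(w, leaf)
    return tree


def evolve_alignment(spec: SimSpec, tree: PhyloTree | None = None, rng=None) -> Alignment:
    """Evolve sequences along a tree: uniform root sequence, then on each edge
    every site substitutes independently (to a uniformly chosen different state)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = random_tree(spec.n_taxa, rng)
    states = states_for(spec.alphabet_kind)
    s = len(states)
    L = spec.sites

    root = min(u for u in tree.adj if not tree.is_leaf(u))
    seqs: dict[int, np.ndarray] = {root: rng.integers(0, s, size=L)}
    stack = [(root, -1)]
    while stack:
        u, parent = stack.pop()
        for v in tree.adj[u]:
            if v == parent:
                continue
            child = seqs[u].copy()
            mutate = rng.random(L) < spec.sub_prob
            shift = rng.integers(1, s, size=int(mutate.sum()))
            child[mutate] = (child[mutate] + shift) % s
            seqs[v] = child
            stack.append((v, u))
    sequences = tuple(
        "".join(states[c] for c in seqs[leaf]) for leaf in range(tree.n_taxa)
    )
    return Alignment(taxa=tree.taxa, sequences=sequences, alphabet_kind=spec.alphabet_kind)


def simulate_pair(
    n: int, sites: int, rng, alphabet_kind: str = "dna", sub_prob: float = 0.1
) -> tuple[PhyloTree, Alignment]:
    """Convenience: a random true tree and an alignment evolved along it."""
    tree = random_tree(n, rng)
    spec = SimSpec(n_taxa=n, sites=sites, alphabet_kind=alphabet_kind, sub_prob=sub_prob)
    aln = evolve_alignment(spec, tree=tree, rng=rng)
    return tree, aln
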