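"""Tree sampling on the original alignment: candidate-set initialization,
perturbation (random NNIs or the parsimony ratchet), hill-climbing, the
low-score threshold used to gate bootstrap rescoring, and the stopping rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .costs import CostModel
from .patterns import PatternAlignment
from .scoring import score_tree, tree_total
from .trees import PhyloTree, hill_climb_spr, random_nni_perturb, random_stepwise_addition

log = logging.getLogger(__name__)

#: memory bound on the multiset of qualifying tree scores
S_CAP = 100_000


@dataclass
class Candidate:
    tree: PhyloTree
    total: int
    key: frozenset
    born: int


@dataclass
class SearchState:
    """State of the exploration phase over the original alignment."""

    candidates: list[Candidate]
    first_tree: PhyloTree  # very first stepwise-addition tree (fixes pattern order)
    n_prime: int
    score_set: list[int] = field(default_factory=list)
    mp_max: float = math.inf
    unsuccessful: int = 0
    iterations: int = 0
    next_born: int = 0
    stop_reason: str = ""

    def best(self) -> Candidate:
        return min(self.candidates, key=lambda c: (c.total, c.born))

    def totals(self) -> list[int]:
        return [c.total for c in self.candidates]

    def update_mp_max(self) -> None:
        if self.score_set:
            self.mp_max = float(
                math.floor(np.quantile(self.score_set, 0.10, method="linear"))
            )


def stopping_horizon(n: int) -> int:
    """Number of sequences rounded up to the nearest hundred."""
    if n < 4:
        raise ValueError("need at least 4 taxa")
    return math.ceil(n / 100) * 100


def init_candidate_set(
    pa: PatternAlignment,
    cm: CostModel,
    radius: int | None,
    rng,
    starts: int = 100,
    keep: int = 5,
    n_prime: int | None = None,
) -> SearchState:
    """Build ``starts`` locally optimal trees (random stepwise addition + SPR
    hill climb), sort by score, keep the first ``keep`` distinct ones."""
    first_tree: PhyloTree | None = None
    results: list[tuple[int, int, PhyloTree]] = []
    for i in range(starts):
        t = random_stepwise_addition(pa, cm, rng)
        if first_tree is None:
            first_tree = t.copy()
        climbed = hill_climb_spr(t, pa, cm, radius)
        results.append((tree_total(climbed, pa, cm), i, climbed))
    results.sort(key=lambda r: (r[0], r[1]))
    candidates: list[Candidate] = []
    seen: set[frozenset] = set()
    for total, _, tree in results:
        key = tree.topology_key()
        if key in seen:
            continue
        seen.add(key)
        candidates.append(Candidate(tree=tree, total=total, key=key, born=len(candidates)))
        if len(candidates) == keep:
            break
    state = SearchState(
        candidates=candidates,
        first_tree=first_tree,
        n_prime=n_prime if n_prime is not None else stopping_horizon(pa.n_taxa),
    )
    state.next_born = len(candidates)
    return state


def perturb(
    state: SearchState,
    pa: PatternAlignment,
    cm: CostModel,
    radius: int | None,
    rng,
    nni_fraction: float = 0.5,
    ratchet_fraction: float = 0.5,
) -> PhyloTree:
    """Pick a candidate tree uniformly; with probability 1/2 perturb it by
    random NNIs, otherwise run the parsimony ratchet (hill climb under
    weights with a random half of the informative site slots duplicated)."""
    t_c = state.candidates[int(rng.integers(len(state.candidates)))].tree
    if rng.random() < 0.5:
        return random_nni_perturb(t_c, nni_fraction, rng)
    extra = rng.multivariate_hypergeometric(
        pa.weights, math.ceil(ratchet_fraction * pa.m)
    )
    perturbed = pa.weights + extra.astype(np.int64)
    return hill_climb_spr(t_c, pa, cm, radius, weights=perturbed)


def exploration_loop(
    state: SearchState,
    pa: PatternAlignment,
    cm: CostModel,
    radius: int | None,
    rng,
    bootstrap_hook=None,
    nni_fraction: float = 0.5,
    ratchet_fraction: float = 0.5,
) -> SearchState:
    """Alternate perturbation and hill climbing until ``n_prime`` consecutive
    unsuccessful steps.

    A step is successful iff the climbed tree scores strictly below the best
    candidate.  Every tree accepted during a climb whose total is below the
    current threshold is added to the score multiset and passed to
    ``bootstrap_hook(tree, psv)``; the threshold is reset to the lower
    10%-quantile of the multiset after each step.
    """
    while state.unsuccessful < state.n_prime:
        t_star = perturb(state, pa, cm, radius, rng, nni_fraction, ratchet_fraction)

        def on_accept(tree, psv):
            if psv.total < state.mp_max:
                if len(state.score_set) < S_CAP:
                    state.score_set.append(psv.total)
                if bootstrap_hook is not None:
                    bootstrap_hook(tree, psv)

        climbed = hill_climb_spr(t_star, pa, cm, radius, on_accept=on_accept)
        total = tree_total(climbed, pa, cm)

        totals = state.totals()
        success = total < min(totals)
        key = climbed.topology_key()
        if total <= max(totals) and all(c.key != key for c in state.candidates):
            worst = max(state.candidates, key=lambda c: (c.total, -c.born))
            idx = state.candidates.index(worst)
            state.candidates[idx] = Candidate(
                tree=climbed, total=total, key=key, born=state.next_born
            )
            state.next_born += 1
        state.unsuccessful = 0 if success else state.unsuccessful + 1
        state.update_mp_max()
        state.iterations += 1
        log.debug(
            "iter=%d best=%d mp_max=%s unsuccessful=%d/%d",
            state.iterations,
            min(state.totals()),
            state.mp_max,
            state.unsuccessful,
            state.n_prime,
        )
    state.stop_reason = f"{state.n_prime} consecutive unsuccessful hill-climbing steps"
    return state
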