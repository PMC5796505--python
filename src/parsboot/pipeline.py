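"""End-to-end analysis: bootstrap weight generation, candidate-set search on
the original alignment with replicate rescoring of every qualifying tree,
refinement of the per-replicate best trees, and support summarization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bootstrap import (
    BootstrapReplicate,
    SupportedTree,
    attach_order,
    majority_consensus,
    make_replicates,
    offer_tree,
    refine,
    support_on_best_tree,
)
from .costs import CostModel, all_pattern_lower_bounds
from .patterns import Alignment, PatternAlignment, compress_informative
from .scoring import ReplicateOrder, score_tree
from .search import SearchState, exploration_loop, init_candidate_set
from .trees import PhyloTree, write_newick


@dataclass
class PipelineResult:
    best_tree: PhyloTree
    best_total: int
    supported: SupportedTree
    consensus: SupportedTree
    replicates: list[BootstrapReplicate]
    state: SearchState
    report: dict


def run_pipeline(
    data: Alignment | PatternAlignment,
    cm: CostModel,
    B: int = 1000,
    radius: int | None = 6,
    seed: int | None = None,
    rng=None,
    starts: int = 100,
    keep: int = 5,
    n_prime: int | None = None,
    nni_fraction: float = 0.5,
    ratchet_fraction: float = 0.5,
    use_abort: bool = True,
    consensus_threshold: float = 50.0,
) -> PipelineResult:
    """Run the full search + bootstrap approximation.

    All randomness flows from one generator seeded with ``seed`` in a fixed
    draw order (replicate weights first, then every search decision), so runs
    with the same seed are bit-reproducible.
    """
    pa = compress_informative(data) if isinstance(data, Alignment) else data
    if rng is None:
        rng = np.random.default_rng(seed)
    bounds = all_pattern_lower_bounds(pa, cm)

    reps = make_replicates(pa, B, rng)
    state = init_candidate_set(
        pa, cm, radius, rng, starts=starts, keep=keep, n_prime=n_prime
    )
    order = ReplicateOrder.from_first_tree_scores(
        score_tree(state.first_tree, pa, cm).scores
    )
    attach_order(reps, order)

    def hook(tree, psv):
        offer_tree(tree, psv, reps, bounds, use_abort=use_abort)

    exploration_loop(
        state,
        pa,
        cm,
        radius,
        rng,
        bootstrap_hook=hook,
        nni_fraction=nni_fraction,
        ratchet_fraction=ratchet_fraction,
    )

    refine(reps, pa, cm, radius)

    best = state.best()
    supported = support_on_best_tree(best.tree, reps)
    consensus = majority_consensus(reps, threshold=consensus_threshold)
    report = {
        "n_taxa": pa.n_taxa,
        "informative_sites": pa.m,
        "patterns": pa.k,
        "best_mp_total": best.total,
        "iterations": state.iterations,
        "stop_reason": state.stop_reason,
        "n_prime": state.n_prime,
        "replicates": B,
        "spr_radius": radius,
        "seed": seed,
    }
    return PipelineResult(
        best_tree=best.tree,
        best_total=best.total,
        supported=supported,
        consensus=consensus,
        replicates=reps,
        state=state,
        report=report,
    )


def write_outputs(result: PipelineResult, prefix) -> list[Path]:
    """Write the best tree with supports, the consensus tree, per-replicate
    best scores (TSV) and a short run report next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    p = prefix.with_suffix(".besttree.nwk")
    p.write_text(result.supported.newick() + "\n")
    paths.append(p)

    p = prefix.with_suffix(".consensus.nwk")
    p.write_text(result.consensus.newick() + "\n")
    paths.append(p)

    p = prefix.with_suffix(".replicates.tsv")
    lines = ["replicate\tbest_score"]
    lines += [f"{rep.index}\t{int(rep.best_score)}" for rep in result.replicates]
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)

    p = prefix.with_suffix(".report.txt")
    p.write_text("".join(f"{k}: {v}\n" for k, v in result.report.items()))
    paths.append(p)

    p = prefix.with_suffix(".mptree.nwk")
    p.write_text(write_newick(result.best_tree) + "\n")
    paths.append(p)
    return paths
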