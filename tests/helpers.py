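"""Small constructors shared across test modules."""

from __future__ import annotations

import numpy as np

from parsboot import Alignment, PhyloTree, parse_newick
from parsboot.patterns import PatternAlignment
from parsboot.scoring import encode_column


def pa_from_columns(columns, weights=None, alphabet_kind="dna", taxa=None) -> PatternAlignment:
    """Build a PatternAlignment directly from column strings (no filtering)."""
    matrix = np.stack([encode_column(c, alphabet_kind) for c in columns], axis=1)
    n = matrix.shape[0]
    if taxa is None:
        taxa = tuple(f"t{i + 1}" for i in range(n))
    w = np.ones(len(columns), dtype=np.int64) if weights is None else np.asarray(weights, dtype=np.int64)
    return PatternAlignment(taxa=tuple(taxa), matrix=matrix.astype(np.int8), weights=w, alphabet_kind=alphabet_kind)


def aln_from_rows(rows, alphabet_kind="dna", taxa=None) -> Alignment:
    """Alignment from one sequence string per taxon."""
    n = len(rows)
    if taxa is None:
        taxa = tuple(f"t{i + 1}" for i in range(n))
    return Alignment(taxa=tuple(taxa), sequences=tuple(rows), alphabet_kind=alphabet_kind)


def quartet(taxa=("t1", "t2", "t3", "t4")) -> PhyloTree:
    """The ((t1,t2),(t3,t4)) topology."""
    return parse_newick(f"(({taxa[0]},{taxa[1]}),({taxa[2]},{taxa[3]}));", taxa=taxa)


def columns_of(aln: Alignment):
    """Iterate alignment columns as strings."""
    for j in range(aln.length):
        yield "".join(seq[j] for seq in aln.sequences)
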