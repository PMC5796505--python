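"""Alignment input and compression into weighted parsimony-informative site patterns.

A tree's parsimony score only depends on the parsimony-informative columns of
the alignment, grouped into distinct patterns with integer multiplicities, so
everything downstream works on :class:`PatternAlignment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

DNA_STATES = "ACGT"
PROTEIN_STATES = "ARNDCQEGHILKMFPSTWYV"

#: code used for gaps, '?', and every ambiguity / unrecognized character
MISSING = -1


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


class NoSignalError(ValueError):
    """Alignment has no parsimony-informative site; tree search cannot proceed."""


def states_for(alphabet_kind: str) -> str:
    if alphabet_kind == "dna":
        return DNA_STATES
    if alphabet_kind == "protein":
        return PROTEIN_STATES
    raise ValueError(f"unknown alphabet kind: {alphabet_kind!r}")


@dataclass(frozen=True)
class Alignment:
    """A plain MSA: ordered taxa and one equal-length sequence per taxon."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    alphabet_kind: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa / sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        states_for(self.alphabet_kind)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        """Integer state codes, shape (n_taxa, length); MISSING for non-states."""
        states = states_for(self.alphabet_kind)
        lut = np.full(256, MISSING, dtype=np.int8)
        for i, s in enumerate(states):
            lut[ord(s)] = i
        if self.alphabet_kind == "dna":
            lut[ord("U")] = states.index("T")
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii", errors="replace"), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)
        return lut[raw]


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_alignment(path, fmt: str, alphabet_kind: str) -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    Characters are upper-cased; anything outside the state alphabet (gaps,
    '?', IUPAC ambiguity codes, ...) is kept and later encoded as missing.
    """
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path}")
        taxa = tuple(r.id for r in records)
        seqs = tuple(_normalize(str(r.seq)) for r in records)
    elif fmt == "phylip":
        msa = None
        err: Exception | None = None
        for schema in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                msa = AlignIO.read(str(path), schema)
                break
            except Exception as exc:  # try the next PHYLIP flavour
                err = exc
        if msa is None:
            raise AlignmentError(f"could not parse {path} as PHYLIP: {err}")
        taxa = tuple(r.id for r in msa)
        seqs = tuple(_normalize(str(r.seq)) for r in msa)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return Alignment(taxa=taxa, sequences=seqs, alphabet_kind=alphabet_kind)


@dataclass
class PatternAlignment:
    """Parsimony-informative site patterns with integer weights.

    ``matrix`` has shape (n_taxa, k): one state code per taxon per pattern,
    with ``MISSING`` (-1) for unknown states.  ``weights[i]`` is the number of
    informative alignment columns equal to pattern i; their sum is ``m``.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray  # int8, (n_taxa, k)
    weights: np.ndarray  # int64, (k,)
    alphabet_kind: str
    _caches: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def m(self) -> int:
        return int(self.weights.sum())

    @property
    def n_states(self) -> int:
        return len(states_for(self.alphabet_kind))

    def pattern(self, i: int) -> np.ndarray:
        return self.matrix[:, i]

    def with_weights(self, weights: np.ndarray) -> "PatternAlignment":
        """Same patterns under a different weight vector (shares caches)."""
        w = np.asarray(weights, dtype=np.int64)
        if w.shape != self.weights.shape:
            raise ValueError("weight vector length mismatch")
        pa = PatternAlignment(self.taxa, self.matrix, w, self.alphabet_kind)
        pa._caches = self._caches
        return pa

    def fitch_masks(self) -> np.ndarray:
        """Per-leaf per-pattern state bitmasks (uint32); missing = all states."""
        cached = self._caches.get("fitch")
        if cached is None:
            full = np.uint32((1 << self.n_states) - 1)
            masks = np.where(
                self.matrix >= 0,
                np.left_shift(np.uint32(1), self.matrix.clip(min=0).astype(np.uint32)),
                full,
            ).astype(np.uint32)
            cached = self._caches["fitch"] = masks
        return cached

    def sankoff_leaf_vectors(self, cost_key, cost: np.ndarray, inf: int) -> np.ndarray:
        """Leaf cost vectors (n_taxa, k, s): 0 at observed state(s), inf elsewhere."""
        cached = self._caches.get(("sankoff", cost_key))
        if cached is None:
            s = cost.shape[0]
            vec = np.full((self.n_taxa, self.k, s), inf, dtype=np.int64)
            obs = self.matrix >= 0
            taxon_idx, pat_idx = np.nonzero(obs)
            vec[taxon_idx, pat_idx, self.matrix[obs]] = 0
            vec[~obs] = 0
            cached = self._caches[("sankoff", cost_key)] = vec
        return cached


def is_informative(column: np.ndarray) -> bool:
    """Standard definition: >=2 distinct non-missing states each in >=2 taxa."""
    observed = column[column >= 0]
    if observed.size == 0:
        return False
    _, counts = np.unique(observed, return_counts=True)
    return int((counts >= 2).sum()) >= 2


def compress_informative(aln: Alignment) -> PatternAlignment:
    """Drop non-informative columns and merge identical ones with summed weights."""
    if aln.n_taxa < 4:
        raise AlignmentError("need at least 4 taxa for tree search")
    enc = aln.encoded()
    keep = [j for j in range(aln.length) if is_informative(enc[:, j])]
    if not keep:
        raise NoSignalError("alignment contains no parsimony-informative site")
    informative = enc[:, keep]
    # merge equal columns; order of first occurrence is preserved
    seen: dict[bytes, int] = {}
    cols: list[np.ndarray] = []
    weights: list[int] = []
    for j in range(informative.shape[1]):
        col = informative[:, j]
        key = col.tobytes()
        if key in seen:
            weights[seen[key]] += 1
        else:
            seen[key] = len(cols)
            cols.append(col)
            weights.append(1)
    matrix = np.stack(cols, axis=1).astype(np.int8)
    return PatternAlignment(
        taxa=aln.taxa,
        matrix=matrix,
        weights=np.array(weights, dtype=np.int64),
        alphabet_kind=aln.alphabet_kind,
    )
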