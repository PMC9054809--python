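"""IUPAC degenerate consensus motifs from pre-aligned boundary sequences.

Each column of an equal-length alignment is collapsed to the minimal IUPAC
symbol covering its observed bases (union consensus, matching the degenerate
motifs conventionally printed for conserved spacer regions, e.g. W = A/T,
H = A/T/C, M = A/C).  A frequency threshold mode covers only bases occurring
at frequency >= t; t = 0 reproduces the union.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = ["ConsensusMotif", "consensus", "iupac_symbol"]

# frozenset of bases -> minimal covering IUPAC symbol
_SYMBOL_BY_SET = {
    frozenset(expansion): symbol
    for symbol, expansion in ambiguous_dna_values.items()
}


def iupac_symbol(bases) -> str:
    s = frozenset(b.upper().replace("U", "T") for b in bases)
    if not s:
        raise ValueError("empty base set has no IUPAC symbol")
    return _SYMBOL_BY_SET[s]


@dataclass
class ConsensusMotif:
    boundary: tuple[str, str] | None
    consensus: str
    n_sequences: int
    column_sets: list[frozenset]


def consensus(aligned: list[str], gap_policy: str = "ignore",
              threshold: float = 0.0,
              boundary: tuple[str, str] | None = None) -> ConsensusMotif:
    """Column-wise IUPAC consensus of >= 2 equal-length aligned sequences.

    ``gap_policy='ignore'`` drops gap characters from each column before
    collapsing; ``'majority'`` emits ``-`` for columns where gaps are the
    majority state.  ``threshold`` keeps only bases with column frequency
    >= threshold (0 = union of all observed bases).
    """
    if not aligned or len(aligned) < 2:
        raise ValueError("consensus needs at least 2 sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise ValueError("aligned sequences must have equal length")
    if gap_policy not in ("ignore", "majority"):
        raise ValueError("gap_policy must be 'ignore' or 'majority'")
    seqs = [s.upper().replace("U", "T") for s in aligned]
    symbols = []
    column_sets = []
    for i in range(length):
        col = [s[i] for s in seqs]
        gaps = sum(1 for b in col if b in "-.")
        if gap_policy == "majority" and gaps * 2 > len(col):
            symbols.append("-")
            column_sets.append(frozenset())
            continue
        bases = [b for b in col if b in "ACGT"]
        if not bases:
            symbols.append("N")
            column_sets.append(frozenset("ACGT"))
            continue
        freq = Counter(bases)
        kept = {b for b, k in freq.items() if k / len(bases) >= threshold}
        if not kept:
            kept = set(freq)
        column_sets.append(frozenset(kept))
        symbols.append(iupac_symbol(kept))
    return ConsensusMotif(boundary, "".join(symbols), len(aligned), column_sets)
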