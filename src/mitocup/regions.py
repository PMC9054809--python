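"""Boundary elements (spacers/overlaps) and gene order on circular genomes.

Adjacent annotated features either overlap (OL), leave an intergenic spacer
(IGS), or abut exactly (no element).  Overlap and gap lengths are plain
interval arithmetic after unrolling the circle, so totals are invariant under
genome rotation.  Opposite-strand overlaps (e.g. trnW/trnC in flies) are
treated identically to same-strand ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genome_io import GeneFeature, MitoGenome

__all__ = ["BoundaryElement", "GeneOrder", "find_boundaries", "gene_order",
           "compare_orders", "boundary_table"]


@dataclass
class BoundaryElement:
    upstream: str
    downstream: str
    kind: str          # IGS | OL
    length: int
    sequence: str      # forward strand

    def involves(self, name: str) -> bool:
        return name in (self.upstream, self.downstream)


@dataclass
class GeneOrder:
    """Rotation-normalized arrangement of (gene, strand) pairs."""

    arrangement: list[tuple[str, str]]
    reference_label: str = ""


def _unrolled(features: list[GeneFeature], L: int) -> list[tuple[GeneFeature, int, int]]:
    out = []
    for f in features:
        end = f.end + L if f.wraps_origin else f.end
        out.append((f, f.start, end))
    out.sort(key=lambda t: t[1])
    return out


def find_boundaries(genome: MitoGenome, exclude_cr: bool = True) -> list[BoundaryElement]:
    """Emit one OL or IGS element per non-abutting adjacent feature pair.

    With ``exclude_cr`` (the default, matching the usual "IGS total excluding
    the control region" convention) boundaries flanking the control region and
    the CR itself are skipped.
    """
    feats = _unrolled(genome.features, genome.length)
    if len(feats) < 2:
        return []
    L = genome.length
    seq2 = genome.sequence * 2
    elements: list[BoundaryElement] = []
    for i, (cur, cs, ce) in enumerate(feats):
        if i + 1 < len(feats):
            nxt, ns, ne = feats[i + 1]
        else:
            nxt, ns, ne = feats[0]
            ns, ne = ns + L, ne + L
        gap = ns - ce
        if gap > 0:
            elements.append(BoundaryElement(cur.name, nxt.name, "IGS", gap,
                                            seq2[ce:ns]))
        elif gap < 0:
            if ne <= ce:  # nested feature
                warnings.warn(
                    f"feature {nxt.name} nested inside {cur.name}; "
                    "reporting OL of the shorter feature's length"
                )
                ol = ne - ns
            else:
                ol = ce - ns
            elements.append(BoundaryElement(cur.name, nxt.name, "OL", ol,
                                            seq2[ns:ns + ol]))
    if exclude_cr:
        elements = [e for e in elements if not e.involves("CR")]
    return elements


def boundary_table(genome: MitoGenome, exclude_cr: bool = True) -> pd.DataFrame:
    rows = [
        {"accession": genome.accession, "upstream": e.upstream,
         "downstream": e.downstream, "kind": e.kind, "length": e.length,
         "sequence": e.sequence}
        for e in find_boundaries(genome, exclude_cr=exclude_cr)
    ]
    return pd.DataFrame(rows, columns=["accession", "upstream", "downstream",
                                       "kind", "length", "sequence"])


def gene_order(genome: MitoGenome, include_cr: bool = False) -> GeneOrder:
    """Rotation-normalized gene order, anchored at trnI when present."""
    feats = [f for f in sorted(genome.features, key=lambda f: f.start)
             if include_cr or f.kind != "control_region"]
    if not feats:
        raise ValueError("genome has no features")
    names = [(f.name, f.strand) for f in feats]
    anchor_names = [n for n, _ in names]
    if "trnI" in anchor_names:
        k = anchor_names.index("trnI")
    else:
        k = min(range(len(names)), key=lambda i: names[i][0])
    return GeneOrder(names[k:] + names[:k], reference_label=genome.accession)


def compare_orders(a: GeneOrder, b: GeneOrder) -> dict[str, list]:
    """Name-level differences between two arrangements.

    ``insertions``: genes in *b* absent from *a*; ``deletions``: the reverse;
    ``transpositions``: genes common to both whose relative order differs
    (genes outside a longest common subsequence of the shared-gene orders).
    Empty lists in every slot iff the arrangements are identical.
    """
    names_a = [n for n, _ in a.arrangement]
    names_b = [n for n, _ in b.arrangement]
    set_a, set_b = set(names_a), set(names_b)
    insertions = [n for n in names_b if n not in set_a]
    deletions = [n for n in names_a if n not in set_b]
    common_a = [n for n in names_a if n in set_b]
    common_b = [n for n in names_b if n in set_a]
    lcs = _lcs(common_a, common_b)
    transpositions = sorted(set(common_a) - set(lcs))
    strand_changes = [
        n for n in set_a & set_b
        if dict(a.arrangement)[n] != dict(b.arrangement)[n]
    ]
    return {
        "insertions": insertions,
        "deletions": deletions,
        "transpositions": transpositions,
        "strand_changes": sorted(strand_changes),
    }


def orders_identical(a: GeneOrder, b: GeneOrder) -> bool:
    return all(not v for v in compare_orders(a, b).values())


def _lcs(x: list[str], y: list[str]) -> list[str]:
    n, m = len(x), len(y)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            dp[i][j] = (dp[i + 1][j + 1] + 1 if x[i] == y[j]
                        else max(dp[i + 1][j], dp[i][j + 1]))
    out, i, j = [], 0, 0
    while i < n and j < m:
        if x[i] == y[j]:
            out.append(x[i]); i += 1; j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out
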