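"""Nucleotide composition, AT/GC content and strand skews.

AT skew = (A - T)/(A + T), GC skew = (G - C)/(G + C), computed over
unambiguous bases only; IUPAC ambiguity codes are counted separately and
excluded from every fraction so the skews stay well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import MitoGenome, extract_feature_sequence
from .regions import find_boundaries

__all__ = ["CompositionProfile", "CodonPositionProfile", "composition",
           "position_composition", "region_composition"]

NAN = float("nan")


@dataclass
class CompositionProfile:
    a: int
    t: int
    g: int
    c: int
    n_ambiguous: int

    @property
    def n_unambiguous(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def at_content(self) -> float:
        n = self.n_unambiguous
        return (self.a + self.t) / n if n else NAN

    @property
    def gc_content(self) -> float:
        n = self.n_unambiguous
        return (self.g + self.c) / n if n else NAN

    @property
    def at_skew(self) -> float:
        d = self.a + self.t
        return (self.a - self.t) / d if d else NAN

    @property
    def gc_skew(self) -> float:
        d = self.g + self.c
        return (self.g - self.c) / d if d else NAN


@dataclass
class CodonPositionProfile:
    """Pooled base content at codon positions 1-3 of a set of CDSs."""

    at1: float
    at2: float
    at3: float
    gc1: float
    gc2: float
    gc3: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2

    @property
    def at12(self) -> float:
        return (self.at1 + self.at2) / 2


def composition(seq: str) -> CompositionProfile:
    s = seq.upper()
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    return CompositionProfile(a, t, g, c, len(s) - a - t - g - c)


def position_composition(cds_list: list[str]) -> CodonPositionProfile:
    """Per-codon-position composition pooled over in-frame CDSs.

    Trailing partial codons (incomplete stops) are dropped before counting.
    """
    profs = []
    for pos in range(3):
        bases = []
        for cds in cds_list:
            s = cds.upper()
            s = s[: len(s) - len(s) % 3]
            bases.append(s[pos::3])
        profs.append(composition("".join(bases)))
    if all(p.n_unambiguous == 0 for p in profs):
        return CodonPositionProfile(NAN, NAN, NAN, NAN, NAN, NAN)
    return CodonPositionProfile(
        at1=profs[0].at_content, at2=profs[1].at_content, at3=profs[2].at_content,
        gc1=profs[0].gc_content, gc2=profs[1].gc_content, gc3=profs[2].gc_content,
    )


_REGION_KINDS = {
    "PCG_concat": "PCG",
    "tRNA_concat": "tRNA",
    "rRNA_concat": "rRNA",
    "CR": "control_region",
}


def region_composition(genome: MitoGenome) -> pd.DataFrame:
    """Composition per (region class, strand) as a tidy table.

    Region classes: whole mitogenome (WMG, forward strand), concatenated
    PCG/tRNA/rRNA (reading direction), control region, concatenated spacers.
    Strand rows ``J``/``N`` restrict to genes encoded on that strand.
    """
    rows = []

    def add(region: str, strand: str, seq: str) -> None:
        p = composition(seq)
        rows.append({
            "accession": genome.accession, "region": region, "strand": strand,
            "length": len(seq), "A": p.a, "T": p.t, "G": p.g, "C": p.c,
            "at_content": p.at_content, "gc_content": p.gc_content,
            "at_skew": p.at_skew, "gc_skew": p.gc_skew,
        })

    add("WMG", "both", genome.sequence)
    for region, kind in _REGION_KINDS.items():
        feats = genome.features_of_kind(kind)
        if not feats:
            continue
        add(region, "both",
            "".join(extract_feature_sequence(genome, f) for f in feats))
        if kind != "control_region":
            for strand in ("J", "N"):
                sub = [f for f in feats if f.strand == strand]
                if sub:
                    add(region, strand,
                        "".join(extract_feature_sequence(genome, f) for f in sub))
    igs = [e.sequence for e in find_boundaries(genome, exclude_cr=True)
           if e.kind == "IGS"]
    if igs:
        add("IGS_concat", "both", "".join(igs))
    return pd.DataFrame(rows)


def round_profile(value: float, kind: str) -> float:
    """Reporting convention: percentages to 2 decimals, skews to 3."""
    if math.isnan(value):
        return value
    return round(value * 100, 2) if kind == "percent" else round(value, 3)
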