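"""Codon counting, RSCU, GC3s and the effective number of codons (ENc)
under the invertebrate mitochondrial code (translation table 5).

Table 5 has no single-codon amino acids: 12 two-fold families, 6 four-fold
families, one six-fold family (Leu) and one eight-fold family (Ser,
TCN + AGN), for 62 sense codons and stops TAA/TAG.  The theoretical ENc
range is therefore [20, 62] (the familiar "20 to 61" applies to the standard
code); values are reported unclamped.

Two ENc estimators are provided:

* ``wright``  -- Wright's (1990) family homozygosity
  F-hat = (n * sum p_i^2 - 1)/(n - 1), class-averaged, with the conventional
  missing-family imputation (families with n < 2 or undefined F-hat take the
  mean F-hat of their degeneracy class; a wholly absent class is rescaled
  out).
* ``sun2012`` -- the pseudocount homozygosity estimator
  F_j = sum_i ((n_ij + 1)/(n_j + m_j))^2 with codon-count-weighted class
  averages, which is defined for every gene including ones with rare amino
  acids.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS", "STOP_CODONS", "FAMILIES", "DEGENERACY_CLASSES",
    "CodonUsageTable", "count_codons", "rscu", "enc", "gc3s", "at3",
]

NAN = float("nan")
_BASES = "TCAG"

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS = tuple(sorted(_TABLE5.stop_codons))          # ('TAA', 'TAG')
SENSE_CODONS = tuple(sorted(_TABLE5.forward_table))       # 62 codons
AA_OF = dict(_TABLE5.forward_table)

# synonymous families: amino acid -> tuple of codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(AA_OF[_codon], tuple())
FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if AA_OF[c] == aa))
    for aa in FAMILIES
}

# degeneracy class -> number of families in it (table 5: 12x2, 6x4, 1x6, 1x8)
DEGENERACY_CLASSES = Counter(len(v) for v in FAMILIES.values())

# optional split treatment of the 6- and 8-fold families (2+4 / 4+4),
# for sensitivity checks against tools that split by first two codon bases
SPLIT_FAMILIES: dict[str, tuple[str, ...]] = {}
for _aa, _codons in FAMILIES.items():
    if len(_codons) <= 4:
        SPLIT_FAMILIES[_aa] = _codons
    else:
        groups: dict[str, list[str]] = {}
        for c in _codons:
            groups.setdefault(c[:2], []).append(c)
        merged: dict[str, list[str]] = {}
        for prefix, cods in groups.items():
            if len(cods) == 4:
                merged[_aa + "_" + prefix] = cods
            else:
                merged.setdefault(_aa + "_rest", []).extend(cods)
        for k, v in merged.items():
            SPLIT_FAMILIES[k] = tuple(sorted(v))


def count_codons(cds: str, include_stop: bool = False) -> tuple[Counter, int]:
    """Count consecutive non-overlapping triplets of a reading-direction CDS.

    Trailing 1-2 nt (incomplete stop codons) are dropped.  The start codon is
    counted as written.  Returns ``(counts, n_skipped)`` where skipped codons
    contained ambiguity codes or gaps.
    """
    s = cds.upper().replace("U", "T")
    skipped = 0
    counts: Counter = Counter()
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            skipped += 1
            continue
        if codon in STOP_CODONS and not include_stop:
            continue
        counts[codon] += 1
    return counts, skipped


def rscu(counts: Counter) -> dict[str, float]:
    """RSCU_i = n_i / (mean count within the synonymous family).

    Codons of amino acids that never occur get NaN.  Within each observed
    family the RSCU values sum to the family size.
    """
    out: dict[str, float] = {}
    for codons in FAMILIES.values():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                out[c] = NAN
        else:
            mean = total / len(codons)
            for c in codons:
                out[c] = counts.get(c, 0) / mean
    return out


def _wright_fhat(family_counts: list[int]) -> float | None:
    # plug-in homozygosity sum p_i^2, which keeps ENc inside [20, 62] and
    # evaluates to exactly 62 under uniform usage; families with n < 2 carry
    # no information and are imputed from their degeneracy class
    n = sum(family_counts)
    if n < 2:
        return None
    return sum((c / n) ** 2 for c in family_counts)


def enc(counts: Counter, method: str = "wright",
        split_families: bool = False) -> float:
    """Effective number of codons of a sense-codon count map."""
    families = SPLIT_FAMILIES if split_families else FAMILIES
    sense = {c: counts.get(c, 0) for c in SENSE_CODONS}
    if sum(sense.values()) == 0:
        return NAN
    if method == "wright":
        return _enc_wright(sense, families)
    if method == "sun2012":
        return _enc_sun(sense, families)
    raise ValueError(f"unknown ENc method {method!r}")


def _classes(families: dict[str, tuple[str, ...]]) -> dict[int, list[tuple[str, ...]]]:
    by_size: dict[int, list[tuple[str, ...]]] = {}
    for codons in families.values():
        by_size.setdefault(len(codons), []).append(codons)
    return by_size


def _enc_wright(sense: dict[str, int], families) -> float:
    by_size = _classes(families)
    fbar: dict[int, float] = {}
    for size, fams in by_size.items():
        fhats = []
        for codons in fams:
            fh = _wright_fhat([sense[c] for c in codons])
            if fh is not None and fh > 0:
                fhats.append(fh)
        if fhats:
            fbar[size] = sum(fhats) / len(fhats)
    total = 0.0
    max_present = 0
    n_codons_all = sum(size * len(fams) for size, fams in by_size.items())
    for size, fams in by_size.items():
        if size in fbar:
            total += len(fams) / fbar[size]
            max_present += size * len(fams)
    if max_present == 0:
        return NAN
    # classes with no estimable family are rescaled out: the observed classes
    # are extrapolated to the full codon complement
    return total * n_codons_all / max_present


def _enc_sun(sense: dict[str, int], families) -> float:
    by_size = _classes(families)
    total = 0.0
    for size, fams in by_size.items():
        num = 0.0
        den = 0
        for codons in fams:
            n = sum(sense[c] for c in codons)
            m = len(codons)
            fj = sum(((sense[c] + 1) / (n + m)) ** 2 for c in codons)
            num += n * fj
            den += n
        if den == 0:
            total += len(fams)
        else:
            total += len(fams) / (num / den)
    return total


def gc3s(counts: Counter) -> float:
    """G/C fraction at position 3 of synonymous sense codons.

    Under table 5 every sense codon belongs to a family of size >= 2, so this
    equals GC3 over sense codons; the operation is kept distinct for
    generality across genetic codes.
    """
    syn = [c for aa, codons in FAMILIES.items() if len(codons) >= 2
           for c in codons]
    n = sum(counts.get(c, 0) for c in syn)
    if n == 0:
        return NAN
    gc = sum(counts.get(c, 0) for c in syn if c[2] in "GC")
    return gc / n


def at3(counts: Counter) -> float:
    """A/T fraction at position 3 of sense codons."""
    n = sum(counts.get(c, 0) for c in SENSE_CODONS)
    if n == 0:
        return NAN
    return sum(counts.get(c, 0) for c in SENSE_CODONS if c[2] in "AT") / n


@dataclass
class CodonUsageTable:
    """Codon usage of one gene (or a concatenated gene set)."""

    label: str
    counts: Counter = field(default_factory=Counter)
    n_skipped: int = 0

    @classmethod
    def from_cds(cls, cds: str, label: str = "") -> "CodonUsageTable":
        counts, skipped = count_codons(cds, include_stop=True)
        return cls(label=label, counts=counts, n_skipped=skipped)

    @property
    def sense_counts(self) -> Counter:
        return Counter({c: self.counts[c] for c in SENSE_CODONS
                        if self.counts.get(c, 0)})

    @property
    def n_sense(self) -> int:
        return sum(self.sense_counts.values())

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self.sense_counts)

    @property
    def at3(self) -> float:
        return at3(self.sense_counts)

    @property
    def gc3(self) -> float:
        a = self.at3
        return 1 - a if not math.isnan(a) else NAN

    @property
    def gc3s(self) -> float:
        return gc3s(self.sense_counts)

    def enc(self, method: str = "wright") -> float:
        return enc(self.sense_counts, method=method)

    def to_frame(self) -> pd.DataFrame:
        r = self.rscu
        rows = [{"gene": self.label, "codon": c, "aa": AA_OF[c],
                 "count": self.counts.get(c, 0), "rscu": r[c]}
                for c in SENSE_CODONS]
        return pd.DataFrame(rows)
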