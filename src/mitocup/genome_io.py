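"""Read, write and normalize annotated mitochondrial genomes.

Internal coordinates are 0-based half-open on the forward strand; GenBank's
1-based inclusive locations are converted at the I/O boundary.  Strands use
the mitogenomics convention J (majority, ``+``) and N (minority, ``-``).
Gene names are normalized to lowercase canonical symbols (``nad1``..``nad6``,
``nad4l``, ``cox1``..``cox3``, ``cytb``, ``atp6``, ``atp8``, ``trnX`` with
``trnS1/trnS2/trnL1/trnL2`` anticodon disambiguation, ``rrnL``, ``rrnS``,
``CR`` for the control region).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitoGenome",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "extract_feature_sequence",
    "feature_table",
    "normalize_gene_name",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
]

PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cytb", "nad1",
)
TRNA_NAMES = tuple(
    "trn" + x
    for x in ("I Q M W C Y L2 K D G A R N S1 E F H T P S2 L1 V".split())
)
RRNA_NAMES = ("rrnL", "rrnS")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A typed, stranded gene feature on the forward strand.

    ``start``/``end`` are 0-based half-open.  A feature spanning the
    replication origin of a circular genome has ``wraps_origin=True`` and
    covers ``[start, genome_length) U [0, end)``.
    """

    name: str
    kind: str               # PCG | tRNA | rRNA | control_region
    strand: str             # J | N
    start: int
    end: int
    wraps_origin: bool = False
    transl_table: int = 5

    def span_length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class MitoGenome:
    """An annotated (usually circular) mitochondrial genome."""

    accession: str
    organism: str
    topology: str                      # circular | linear
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: f.start)
        for f in self.features:
            if not (0 <= f.start < self.length):
                raise ValueError(f"feature {f.name} start out of range")
            if not f.wraps_origin and f.end > self.length:
                raise ValueError(f"feature {f.name} extends past sequence end")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def rotated(self, offset: int) -> "MitoGenome":
        """Rotate a circular genome so old position ``offset`` becomes 0."""
        if self.topology != "circular":
            raise ValueError("rotation only defined for circular genomes")
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            span = f.span_length(L)
            start = (f.start - offset) % L
            end = start + span
            feats.append(replace(f, start=start, end=end % L if end > L else end,
                                 wraps_origin=end > L))
        return MitoGenome(self.accession, self.organism, self.topology, seq, feats)


# ---------------------------------------------------------------------------
# gene-name normalization

_PCG_ALIASES = {
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND4L": "nad4l", "ND5": "nad5", "ND6": "nad6",
    "NADH1": "nad1", "NADH2": "nad2", "NADH3": "nad3", "NADH4": "nad4",
    "NADH4L": "nad4l", "NADH5": "nad5", "NADH6": "nad6",
    "COI": "cox1", "COII": "cox2", "COIII": "cox3",
    "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
    "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
    "COB": "cytb", "CYTB": "cytb", "CYB": "cytb",
    "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
    **{n.upper(): n for n in PCG_NAMES},
}

_RRNA_ALIASES = {
    "RRNL": "rrnL", "16S": "rrnL", "LRRNA": "rrnL", "L-RRNA": "rrnL",
    "LSU": "rrnL", "16S RIBOSOMAL RNA": "rrnL",
    "RRNS": "rrnS", "12S": "rrnS", "SRRNA": "rrnS", "S-RRNA": "rrnS",
    "SSU": "rrnS", "12S RIBOSOMAL RNA": "rrnS",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# serine/leucine isoacceptors: trnS1 recognizes AGN (anticodon GCU),
# trnS2 recognizes UCN; trnL1 recognizes CUN, trnL2 UUR.
_ISO_BY_CODONS = {
    ("S", "AGN"): "S1", ("S", "GCU"): "S1", ("S", "GCT"): "S1",
    ("S", "UCN"): "S2", ("S", "TCN"): "S2", ("S", "UGA"): "S2", ("S", "TGA"): "S2",
    ("L", "CUN"): "L1", ("L", "CTN"): "L1", ("L", "UAG"): "L1", ("L", "TAG"): "L1",
    ("L", "UUR"): "L2", ("L", "TTR"): "L2", ("L", "UAA"): "L2", ("L", "TAA"): "L2",
}

_CR_PATTERN = re.compile(
    r"d[- ]?loop|control[- _]?region|a\s*\+?\s*t[- ]?rich|at[- ]?rich", re.I
)


def normalize_gene_name(raw: str, kind_hint: str | None = None) -> str | None:
    """Map a heterogeneous annotation label to the canonical symbol.

    Returns ``None`` when the label is not recognized; callers decide how to
    handle the passthrough.
    """
    token = raw.strip()
    up = token.upper().replace("-", "").replace("_", "").replace(" ", "")
    if up in _PCG_ALIASES:
        return _PCG_ALIASES[up]
    key = token.strip().upper()
    if key in _RRNA_ALIASES or up in {k.replace("-", "") for k in _RRNA_ALIASES}:
        return _RRNA_ALIASES.get(key) or _RRNA_ALIASES.get(up.replace("RIBOSOMALRNA", ""))
    for alias, canon in _RRNA_ALIASES.items():
        if up == alias.replace("-", "").replace(" ", ""):
            return canon
    if up == "CR" or _CR_PATTERN.search(token):
        return "CR"
    m = re.match(r"(?:TRN|TRNA[- ]?)([A-Z])(\d)?(?:\(([A-Z]{3})\))?$", key.replace(" ", ""))
    if m:
        aa, num, anti = m.group(1), m.group(2), m.group(3)
        return _trn_name(aa, num, anti)
    m = re.match(r"TRNA[- ]?([A-Z]{3})(\d)?(?:\s*\(([A-Z]{3})\))?$", key)
    if m and m.group(1) in _AA3_TO_1:
        return _trn_name(_AA3_TO_1[m.group(1)], m.group(2), m.group(3))
    return None


def _trn_name(aa: str, num: str | None, codons: str | None) -> str:
    if aa in ("S", "L"):
        if num in ("1", "2"):
            return f"trn{aa}{num}"
        if codons and (aa, codons) in _ISO_BY_CODONS:
            return f"trn{_ISO_BY_CODONS[(aa, codons)]}"
        # undisambiguated serine/leucine: default to the ancestral-order first copy
        return f"trn{aa}1"
    return f"trn{aa}"


# ---------------------------------------------------------------------------
# GenBank I/O

def _location_to_coords(loc) -> tuple[int, int, bool]:
    """Biopython location -> (start, end, wraps_origin), 0-based half-open."""
    if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
        a, b = loc.parts
        # join(start..L, 1..end) encodes an origin-spanning feature
        if int(b.start) == 0 and int(a.end) > int(a.start):
            return int(a.start), int(b.end), True
    return int(loc.start), int(loc.end), False


def _infer_kind(feature_key: str) -> str:
    return {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(
        feature_key, "control_region"
    )


def read_genbank(path) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Control region: taken from ``misc_feature``/``D-loop`` records when
    annotated; otherwise the largest unannotated gap adjacent to ``rrnS`` is
    labelled ``CR``.
    """
    record = SeqIO.read(path, "genbank")
    topology = record.annotations.get("topology", "linear")
    organism = record.annotations.get("organism", "")
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        label = None
        for q in ("gene", "product", "note"):
            if q in feat.qualifiers:
                label = feat.qualifiers[q][0]
                break
        if feat.type == "D-loop":
            label = label or "control region"
        if label is None:
            continue
        name = normalize_gene_name(label)
        kind = _infer_kind(feat.type)
        if name is None:
            if feat.type == "misc_feature":
                continue
            warnings.warn(f"unrecognized gene name {label!r}; keeping as-is")
            name = label
        if name == "CR":
            kind = "control_region"
        start, end, wraps = _location_to_coords(feat.location)
        if end > len(record.seq) or start >= len(record.seq):
            raise ValueError(f"feature {name} outside sequence")
        tt = int(feat.qualifiers.get("transl_table", [5])[0])
        features.append(
            GeneFeature(name, kind, "J" if feat.location.strand != -1 else "N",
                        start, end, wraps, tt)
        )
    genome = MitoGenome(record.id or record.name, organism, topology,
                        str(record.seq), features)
    if not any(f.kind == "control_region" for f in genome.features):
        _detect_control_region(genome)
    return genome


def _detect_control_region(genome: MitoGenome) -> None:
    """Label the largest unannotated gap adjacent to rrnS as CR, in place."""
    feats = genome.features
    if len(feats) < 2:
        return
    L = genome.length
    best = None
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        cur_end = cur.end if not cur.wraps_origin else cur.end + L
        gap = (nxt.start - cur_end) % L if i + 1 < len(feats) else (nxt.start + L - cur_end)
        if gap <= 0:
            continue
        adjacent = "rrnS" in (cur.name, nxt.name)
        if adjacent and (best is None or gap > best[0]):
            best = (gap, cur_end % L)
    if best is not None:
        gap, start = best
        end = start + gap
        genome.features.append(
            GeneFeature("CR", "control_region", "J",
                        start, end % L if end > L else end, wraps_origin=end > L)
        )
        genome.features.sort(key=lambda f: f.start)


def write_genbank(genome: MitoGenome, path) -> None:
    seq = Seq(genome.sequence)
    record = SeqRecord(seq, id=genome.accession, name=genome.accession[:16],
                       description=f"{genome.organism} mitochondrion")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    record.annotations["organism"] = genome.organism
    L = genome.length
    key_by_kind = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "control_region": "misc_feature"}
    for f in genome.features:
        strand = 1 if f.strand == "J" else -1
        if f.wraps_origin:
            loc = CompoundLocation([SimpleLocation(f.start, L, strand),
                                    SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals = {"gene": [f.name]}
        if f.kind == "PCG":
            quals["transl_table"] = [str(f.transl_table)]
        if f.kind == "control_region":
            quals["note"] = ["control region"]
        record.features.append(SeqFeature(loc, type=key_by_kind[f.kind],
                                          qualifiers=quals))
    SeqIO.write(record, path, "genbank")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA -> {id: sequence} (raw sequence statistics input)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Reading-direction sequence of a feature (revcomp for N strand)."""
    if feature not in genome.features:
        raise ValueError("feature does not belong to genome")
    if feature.wraps_origin:
        raw = genome.sequence[feature.start:] + genome.sequence[:feature.end]
    else:
        raw = genome.sequence[feature.start:feature.end]
    return reverse_complement(raw) if feature.strand == "N" else raw


def feature_table(genome: MitoGenome) -> pd.DataFrame:
    rows = [
        {
            "accession": genome.accession,
            "gene": f.name,
            "kind": f.kind,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "length": f.span_length(genome.length),
            "wraps_origin": f.wraps_origin,
        }
        for f in genome.features
    ]
    return pd.DataFrame(rows)
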