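"""Pairwise synonymous/nonsynonymous divergence by Nei-Gojobori (1986)
counting under the invertebrate mitochondrial code.

Synonymous site counts: at each codon position the synonymous fraction of
the possible single-base changes is computed with changes to stop codons
excluded, so S + N = 3 x (number of compared codons).  Observed differences
between codon pairs are averaged with equal weights over all minimal
mutational pathways, excluding pathways that pass through a stop codon
(falling back to all pathways when every one is blocked).  Proportions are
corrected for multiple hits with Jukes-Cantor, d = -(3/4) ln(1 - (4/3) p);
the correction (and therefore dS/dN) is undefined for p >= 3/4.

This counting estimator serves as a transparent, assumption-light measure of
dS/dN; maximum-likelihood codon models are deliberately out of scope, and
externally produced dS/dN tables can be fed to the regression stage instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from statistics import mean, median

import pandas as pd

from .codon_usage import AA_OF, STOP_CODONS

__all__ = ["DivergenceEstimate", "DivergenceSummary", "ng86_pair",
           "panel_divergence", "synonymous_sites", "pathway_differences",
           "jukes_cantor"]

NAN = float("nan")
_BASES = "ACGT"


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3)."""
    if codon in STOP_CODONS:
        raise ValueError("stop codons carry no sites")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if AA_OF[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, pathway-averaged.

    Enumerates every ordering of the differing positions; a pathway is
    discarded when an intermediate codon is a stop codon.  When all pathways
    are blocked, the average is taken over all of them instead.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            if AA_OF.get(cur, None) is not None and AA_OF.get(nxt, None) is not None \
                    and AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def jukes_cantor(p: float) -> float:
    if math.isnan(p):
        return NAN
    if p >= 0.75:
        return NAN
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class DivergenceEstimate:
    gene: str
    pair: tuple[str, str]
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int

    @property
    def ps(self) -> float:
        return self.sd / self.s_sites if self.s_sites > 0 else NAN

    @property
    def pn(self) -> float:
        return self.nd / self.n_sites if self.n_sites > 0 else NAN

    @property
    def ds(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def dn(self) -> float:
        return jukes_cantor(self.pn)

    @property
    def omega(self) -> float:
        ds, dn = self.ds, self.dn
        if math.isnan(ds) or math.isnan(dn) or ds == 0:
            return NAN
        return dn / ds


@dataclass
class DivergenceSummary:
    gene: str
    species: str
    ads: float
    adn: float
    omega_mean: float


def _clean_codons(a: str, b: str):
    """Pairwise codon list with gap/ambiguity/stop codons excluded."""
    for i in range(0, min(len(a), len(b)) - min(len(a), len(b)) % 3, 3):
        ca, cb = a[i:i + 3].upper(), b[i:i + 3].upper()
        if any(x not in _BASES for x in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        yield ca, cb


def ng86_pair(cds_a: str, cds_b: str, gene: str = "",
              pair: tuple[str, str] = ("A", "B")) -> DivergenceEstimate:
    """Nei-Gojobori divergence estimate for two aligned in-frame CDSs."""
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal aligned length")
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for ca, cb in _clean_codons(cds_a, cds_b):
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += 3.0 - (sa + sb) / 2.0
        d_s, d_n = pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
        n_codons += 1
    return DivergenceEstimate(gene, pair, s_sites, n_sites, sd, nd, n_codons)


def panel_divergence(gene_sequences: dict[str, str], gene: str = "",
                     aggregate: str = "mean"):
    """All pairwise NG86 estimates plus per-species panel averages.

    ``aggregate`` chooses how a species' pairwise dS/dN values are combined
    into its adS/adN summary (``mean`` or ``median``).  Returns
    ``(estimates, summaries)``.
    """
    species = sorted(gene_sequences)
    if len(species) < 2:
        raise ValueError("panel needs at least 2 species")
    agg = {"mean": mean, "median": median}[aggregate]
    estimates = [
        ng86_pair(gene_sequences[a], gene_sequences[b], gene=gene, pair=(a, b))
        for i, a in enumerate(species) for b in species[i + 1:]
    ]
    summaries = []
    for sp in species:
        mine = [e for e in estimates if sp in e.pair]
        ds = [e.ds for e in mine if not math.isnan(e.ds)]
        dn = [e.dn for e in mine if not math.isnan(e.dn)]
        om = [e.omega for e in mine if not math.isnan(e.omega)]
        summaries.append(DivergenceSummary(
            gene, sp,
            agg(ds) if ds else NAN,
            agg(dn) if dn else NAN,
            agg(om) if om else NAN,
        ))
    return estimates, summaries


def divergence_table(estimates: list[DivergenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene": e.gene, "speciesA": e.pair[0], "speciesB": e.pair[1],
         "S_sites": e.s_sites, "N_sites": e.n_sites, "Sd": e.sd, "Nd": e.nd,
         "dS": e.ds, "dN": e.dn, "omega": e.omega}
        for e in estimates
    )


def summary_table(summaries: list[DivergenceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene": s.gene, "species": s.species, "adS": s.ads, "adN": s.adn,
         "omega": s.omega_mean}
        for s in summaries
    )
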