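import pytest
from hypothesis import settings

from mitocup.genome_io import GeneFeature, MitoGenome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mitocup.synthetic_data import blepharipa_like_spec, generate_genome


@pytest.fixture(scope="session")
def blepharipa_like():
    """Synthetic genome realizing the published annotation structure."""
    return generate_genome(blepharipa_like_spec(seed=11))


@pytest.fixture()
def tiny_genome():
    """Hand-built 3-gene circular genome with one gap and one overlap.

    Layout on a 60 nt circle: geneA [0,18) J, gap [18,24) 6 nt,
    geneB [24,42) N, overlap 4 nt, geneC [38,56) J, gap [56,60) 4 nt back
    to geneA (circular).
    """
    seq = ("ATGAAATTTGGGCCCTAA" +        # geneA 18
           "TTTTTT" +                     # gap 6
           "ATGCCCAAATTTGGGTAA" +         # geneB 18
           "ATGAAACCCGGGTT" +             # geneC remainder (overlap eats 4)
           "AAAA")
    assert len(seq) == 60
    feats = [
        GeneFeature("geneA", "PCG", "J", 0, 18),
        GeneFeature("geneB", "PCG", "N", 24, 42),
        GeneFeature("geneC", "PCG", "J", 38, 56),
    ]
    return MitoGenome("TINY01", "toy", "circular", seq, feats)
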