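"""Codon counting, RSCU, GC3s and ENc under translation table 5."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocup.codon_usage import (DEGENERACY_CLASSES, FAMILIES, SENSE_CODONS,
                                 STOP_CODONS, CodonUsageTable, at3,
                                 count_codons, enc, gc3s, rscu)


def test_table5_family_structure():
    """Invertebrate mito code: 12x2-fold, 6x4-fold, Leu 6-fold, Ser 8-fold,
    62 sense codons, stops TAA/TAG only."""
    assert dict(DEGENERACY_CLASSES) == {2: 12, 4: 6, 6: 1, 8: 1}
    assert len(SENSE_CODONS) == 62
    assert set(STOP_CODONS) == {"TAA", "TAG"}
    assert set(FAMILIES["S"]) == {"TCT", "TCC", "TCA", "TCG",
                                  "AGT", "AGC", "AGA", "AGG"}
    assert len(FAMILIES["L"]) == 6
    assert set(FAMILIES["M"]) == {"ATA", "ATG"}
    assert set(FAMILIES["W"]) == {"TGA", "TGG"}


class TestCountCodons:
    def test_stop_handling(self):
        counts, _ = count_codons("ATGTTTTAA")
        assert counts == Counter({"ATG": 1, "TTT": 1})
        counts2, _ = count_codons("ATGTTTTAA", include_stop=True)
        assert sum(counts2.values()) == 3

    def test_trailing_partial_codon_dropped(self):
        counts, _ = count_codons("ATGTTTT")
        assert sum(counts.values()) == 2

    def test_ambiguous_codons_skipped_with_tally(self):
        counts, skipped = count_codons("ATGNNNTTT")
        assert skipped == 1 and sum(counts.values()) == 2

    def test_matches_brute_force_triplets(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        counts, _ = count_codons(seq, include_stop=True)
        brute = Counter(seq[i:i + 3] for i in range(0, 900, 3))
        assert counts == brute


class TestRscu:
    def test_uniform_family_gives_one(self):
        counts = Counter({c: 5 for c in FAMILIES["V"]})
        vals = rscu(counts)
        for c in FAMILIES["V"]:
            assert vals[c] == pytest.approx(1.0)

    def test_twofold_definition(self):
        counts = Counter({"AAA": 3, "AAG": 1})
        vals = rscu(counts)
        assert vals["AAA"] == pytest.approx(1.5)
        assert vals["AAG"] == pytest.approx(0.5)

    def test_absent_amino_acid_is_na(self):
        vals = rscu(Counter({"AAA": 1}))
        assert math.isnan(vals["TGT"])

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=400))
    @settings(max_examples=60, deadline=None)
    def test_family_sums_equal_family_size(self, codons):
        vals = rscu(Counter(codons))
        for aa, fam in FAMILIES.items():
            total = sum(vals[c] for c in fam)
            if any(Counter(codons)[c] for c in fam):
                assert total == pytest.approx(len(fam))
            else:
                assert math.isnan(total)


class TestEnc:
    def test_single_codon_per_family_is_20(self):
        counts = Counter({fam[0]: 50 for fam in FAMILIES.values()})
        assert enc(counts, "wright") == pytest.approx(20.0)

    def test_uniform_usage_is_62(self):
        counts = Counter({c: 100 for c in SENSE_CODONS})
        assert enc(counts, "wright") == pytest.approx(62.0)

    def test_empty_counts_na(self):
        assert math.isnan(enc(Counter(), "wright"))

    def test_methods_agree_on_large_uniform_sample(self):
        rng = np.random.default_rng(0)
        codons = rng.choice(SENSE_CODONS, size=3000)
        counts = Counter(codons.tolist())
        w, s = enc(counts, "wright"), enc(counts, "sun2012")
        assert abs(w - s) < 1.0

    def test_concentration_does_not_increase_enc(self):
        """Moving usage onto fewer codons within families lowers ENc."""
        rng = np.random.default_rng(1)
        base = Counter(rng.choice(SENSE_CODONS, size=2000).tolist())
        concentrated = Counter()
        for fam in FAMILIES.values():
            concentrated[fam[0]] += sum(base.get(c, 0) for c in fam)
        assert enc(concentrated, "wright") <= enc(base, "wright") + 1e-9
        assert enc(concentrated, "sun2012") <= enc(base, "sun2012") + 1e-9

    def test_range_bounds_on_random_counts(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            codons = rng.choice(SENSE_CODONS, size=int(rng.integers(200, 2000)))
            counts = Counter(codons.tolist())
            for method in ("wright", "sun2012"):
                val = enc(counts, method)
                assert 20.0 <= val <= 62.0 + 1e-6

    def test_split_family_variant_runs(self):
        counts = Counter({c: 10 for c in SENSE_CODONS})
        val = enc(counts, "wright", split_families=True)
        assert 20.0 <= val <= 64.0


class TestGc3s:
    def test_all_at_ending(self):
        counts = Counter({"AAA": 5, "TTT": 5})
        assert gc3s(counts) == 0.0

    def test_all_gc_ending(self):
        counts = Counter({"AAG": 5, "TTC": 5})
        assert gc3s(counts) == 1.0

    def test_equals_generator_bookkeeping(self):
        """Sampling with a known third-position GC share recovers it."""
        rng = np.random.default_rng(9)
        at_end = [c for c in SENSE_CODONS if c[2] in "AT"]
        gc_end = [c for c in SENSE_CODONS if c[2] in "GC"]
        target = 0.2
        n = 20000
        picks = np.concatenate([
            rng.choice(gc_end, size=int(n * target)),
            rng.choice(at_end, size=n - int(n * target)),
        ])
        counts = Counter(picks.tolist())
        assert gc3s(counts) == pytest.approx(target, abs=1e-9)
        assert at3(counts) == pytest.approx(1 - target, abs=1e-9)


def test_codon_usage_table_wraps_operations(blepharipa_like):
    from mitocup.genome_io import extract_feature_sequence
    f = blepharipa_like.get("nad5")
    t = CodonUsageTable.from_cds(
        extract_feature_sequence(blepharipa_like, f), label="nad5")
    assert t.n_sense == 1716 // 3 - 1          # stop excluded
    assert 20 <= t.enc("sun2012") <= 62
    assert t.at3 > 0.85
    df = t.to_frame()
    assert len(df) == 62 and set(df.columns) == {"gene", "codon", "aa",
                                                 "count", "rscu"}
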