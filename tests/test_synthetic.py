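"""Synthetic genome generator: determinism, targets, divergence plans."""

from collections import Counter

import numpy as np
import pytest

from mitocup.codon_usage import STOP_CODONS, at3, count_codons
from mitocup.genome_io import extract_feature_sequence
from mitocup.regions import find_boundaries, gene_order
from mitocup.synthetic_data import (ANCESTRAL_DIPTERAN_ORDER,
                                    BLEPHARIPA_BOUNDARY_PLAN, SyntheticSpec,
                                    blepharipa_like_spec, diverge_pair,
                                    generate_genome)


class TestGenerateGenome:
    def test_same_seed_bit_identical(self):
        g1 = generate_genome(blepharipa_like_spec(seed=5))
        g2 = generate_genome(blepharipa_like_spec(seed=5))
        assert g1.sequence == g2.sequence
        assert [(f.name, f.start, f.end) for f in g1.features] == \
               [(f.name, f.start, f.end) for f in g2.features]

    def test_different_seed_differs(self):
        g1 = generate_genome(blepharipa_like_spec(seed=5))
        g2 = generate_genome(blepharipa_like_spec(seed=6))
        assert g1.sequence != g2.sequence

    def test_requested_order_realized(self, blepharipa_like):
        order = gene_order(blepharipa_like)
        assert order.arrangement == [
            (g, s) for g, s in ANCESTRAL_DIPTERAN_ORDER if g != "CR"]

    def test_boundary_plan_realized_exactly(self, blepharipa_like):
        els = {(e.upstream, e.downstream): (e.kind, e.length)
               for e in find_boundaries(blepharipa_like, exclude_cr=False)}
        for up, down, kind, length in BLEPHARIPA_BOUNDARY_PLAN:
            assert els[(up, down)] == (kind, length)
        # abutting pairs produce nothing
        assert ("cox1", "trnL2") not in els
        assert ("cox2", "trnK") not in els

    def test_at3_one_constrains_every_codon(self):
        spec = blepharipa_like_spec(seed=2)
        spec.at3_target = 1.0
        g = generate_genome(spec)
        for f in g.features_of_kind("PCG"):
            cds = extract_feature_sequence(g, f)
            trimmed = cds[: len(cds) - len(cds) % 3]
            codons = [trimmed[i:i + 3] for i in range(0, len(trimmed), 3)]
            # skip the start codon and overlap-rewritten termini
            assert all(c[2] in "AT" for c in codons[1:-2]
                       if c not in STOP_CODONS), f.name

    def test_at3_recovered_at_10k_codons(self):
        """Binomial error bound: measured AT3 within +/-0.01 of target."""
        spec = SyntheticSpec(seed=3, at3_target=0.92)
        spec.gene_lengths = dict(spec.gene_lengths)
        spec.gene_lengths["nad5"] = 30000 + 3   # ~10,000 codons, one gene
        spec.boundary_plan = tuple(
            b for b in spec.boundary_plan
            if b[2] != "OL" or "nad5" not in (b[0], b[1]))
        g = generate_genome(spec)
        counts, _ = count_codons(extract_feature_sequence(g, g.get("nad5")))
        assert at3(counts) == pytest.approx(0.92, abs=0.01)

    def test_incomplete_stop_and_start_codons(self, blepharipa_like):
        g = blepharipa_like
        cds = extract_feature_sequence(g, g.get("nad5"))
        assert cds[:3] in ("ATG", "ATA", "ATT", "ATC")
        assert cds[-3:] == "TAA"
        cox2 = extract_feature_sequence(g, g.get("cox2"))
        assert len(cox2) % 3 == 1 and cox2.endswith("T")
        assert extract_feature_sequence(g, g.get("cox1"))[:3] == "TCG"

    def test_no_internal_stops_in_frame(self, blepharipa_like):
        g = blepharipa_like
        for f in g.features_of_kind("PCG"):
            cds = extract_feature_sequence(g, f)
            body = cds[: len(cds) - len(cds) % 3][:-3]
            internal = [body[i:i + 3] for i in range(0, len(body), 3)]
            # overlapping termini may be rewritten by a neighbour; interior
            # codons must stay sense
            assert not any(c in STOP_CODONS for c in internal[2:-2]), f.name

    def test_control_region_runs_and_at(self, blepharipa_like):
        cr = extract_feature_sequence(blepharipa_like, blepharipa_like.get("CR"))
        assert len(cr) == 168
        assert cr.startswith("T" * 15) and cr.endswith("A" * 15)
        at = sum(1 for b in cr if b in "AT") / len(cr)
        assert at > 0.88

    def test_inconsistent_plan_rejected(self):
        spec = blepharipa_like_spec()
        spec.boundary_plan = (("trnI", "trnQ", "OL", 70),) + spec.boundary_plan[1:]
        with pytest.raises(ValueError):
            generate_genome(spec)


class TestDivergePair:
    def test_null_plan_identity(self, blepharipa_like):
        g2, ledger = diverge_pair(blepharipa_like, (0.0, 0.0), seed=1)
        assert g2.sequence == blepharipa_like.sequence
        assert len(ledger) == 0

    def test_ledger_equals_hamming_distance(self, blepharipa_like):
        g2, ledger = diverge_pair(blepharipa_like, (0.05, 0.01), seed=2)
        hamming = sum(a != b for a, b in zip(blepharipa_like.sequence,
                                             g2.sequence))
        assert hamming == len(ledger)

    def test_classes_recovered_by_counting(self, blepharipa_like):
        """Planned synonymous-only divergence yields dN = 0 and dS near the
        Jukes-Cantor-corrected plan at 1000+ codons."""
        from mitocup.divergence import jukes_cantor, ng86_pair
        g2, ledger = diverge_pair(blepharipa_like, (0.10, 0.0), seed=3)
        assert set(ledger["class"]) == {"synonymous"}
        a = extract_feature_sequence(blepharipa_like, blepharipa_like.get("nad5"))
        b = extract_feature_sequence(g2, g2.get("nad5"))
        est = ng86_pair(a, b)
        assert est.nd == 0.0 and est.dn == 0.0
        assert est.ds == pytest.approx(jukes_cantor(0.10), rel=0.10)

    def test_same_seed_same_ledger(self, blepharipa_like):
        _, l1 = diverge_pair(blepharipa_like, (0.05, 0.02), seed=9)
        _, l2 = diverge_pair(blepharipa_like, (0.05, 0.02), seed=9)
        assert l1.equals(l2)

    def test_no_stop_codons_created(self, blepharipa_like):
        g2, _ = diverge_pair(blepharipa_like, (0.2, 0.05), seed=4)
        for f in g2.features_of_kind("PCG"):
            cds = extract_feature_sequence(g2, f)
            body = cds[: len(cds) - len(cds) % 3][:-3]
            codons = [body[i:i + 3] for i in range(0, len(body), 3)]
            assert not any(c in STOP_CODONS for c in codons[2:-2]), f.name

    def test_invalid_plan_rejected(self, blepharipa_like):
        with pytest.raises(ValueError):
            diverge_pair(blepharipa_like, (0.8, 0.0), seed=0)
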