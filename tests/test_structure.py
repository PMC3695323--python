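"""Nested insertions, pre-insertion reconstruction, genotyping, PCR."""

import pytest

from stowaway_kit.miner import find_tir_candidates
from stowaway_kit.sequences import GenomicSequence, revcomp
from stowaway_kit.structure import (GenotypeParams, LocusAnchorError,
                                    PCRParams, PrimerSpec, TSDAbsentError,
                                    classify_locus_variant, detect_nested,
                                    insilico_pcr, polymorphism_report,
                                    reconstruct_preinsertion, LocusVariant)
from stowaway_kit.synthetic import (ElementCopy, FamilySpec,
                                    generate_background, generate_family,
                                    plant_insertions, plant_nested,
                                    simulate_locus_population)


class TestReconstruct:
    def test_inverts_single_insertion(self, clean_family):
        _, _, copies = clean_family
        bg = generate_background(10_000, 0.65, seed=301)
        genome, truth = plant_insertions(bg, copies[:1], 1, seed=302)
        r = truth.records[0]
        assert reconstruct_preinsertion(genome.residues, r.start, r.end) \
            == bg.residues

    def test_length_arithmetic(self, planted_genome):
        _, genome, truth = planted_genome
        r = truth.records[0]
        out = reconstruct_preinsertion(genome.residues, r.start, r.end)
        assert len(out) == len(genome) - (r.end - r.start) - 2

    def test_missing_tsd_is_an_error(self, planted_genome):
        _, genome, truth = planted_genome
        r = truth.records[0]
        broken = genome.residues[:r.end] + "GG" + genome.residues[r.end + 2:]
        with pytest.raises(TSDAbsentError):
            reconstruct_preinsertion(broken, r.start, r.end)


class TestDetectNested:
    def test_intact_element_has_no_nested_hits(self, planted_genome):
        _, genome, truth = planted_genome
        cands = find_tir_candidates(genome)
        for c in cands:
            assert detect_nested(c, genome) == []

    def test_planted_nested_recovered_exactly(self, planted_genome):
        _, genome, truth = planted_genome
        target = truth.records[1]
        inner_cons, _ = generate_family(FamilySpec("in", consensus_length=120),
                                        1, seed=311)
        inner = ElementCopy("in", "in.0", inner_cons)
        g2, t2 = plant_nested(genome, truth, inner, target.copy_id, seed=312)
        in_rec = next(r for r in t2.records if r.nesting_parent)
        out_rec = next(r for r in t2.records if r.copy_id == target.copy_id)
        outer_cand = next(c for c in find_tir_candidates(g2)
                          if (c.start, c.end) == (out_rec.start, out_rec.end))
        nested = detect_nested(outer_cand, g2)
        assert len(nested) == 1
        n = nested[0]
        assert (outer_cand.start + n.inner.start,
                outer_cand.start + n.inner.end) == (in_rec.start, in_rec.end)
        # reconstruction returns the pre-nesting outer copy
        pre_outer = genome.residues[target.start:target.end]
        assert n.reconstructed_outer == pre_outer

    def test_inner_without_tsd_not_reported(self, planted_genome):
        _, genome, truth = planted_genome
        target = truth.records[1]
        inner_cons, _ = generate_family(FamilySpec("in", consensus_length=120),
                                        1, seed=311)
        inner = ElementCopy("in", "in.0", inner_cons)
        g2, t2 = plant_nested(genome, truth, inner, target.copy_id, seed=312)
        in_rec = next(r for r in t2.records if r.nesting_parent)
        out_rec = next(r for r in t2.records if r.copy_id == target.copy_id)
        # destroy the inner element's left TA
        broken = (g2.residues[:in_rec.start - 2] + "GG"
                  + g2.residues[in_rec.start:])
        g3 = GenomicSequence(g2.id, broken)
        outer_cand = next(c for c in find_tir_candidates(g3)
                          if (c.start, c.end) == (out_rec.start, out_rec.end))
        assert detect_nested(outer_cand, g3) == []

    def test_inner_never_overlaps_outer_tirs(self, planted_genome):
        _, genome, truth = planted_genome
        for target in truth.records[:3]:
            inner = ElementCopy("in", "in.0",
                                generate_family(FamilySpec(
                                    "in", consensus_length=100), 1, 313)[0])
            g2, t2 = plant_nested(genome, truth, inner, target.copy_id, 314)
            out_rec = next(r for r in t2.records
                           if r.copy_id == target.copy_id)
            cand = next(c for c in find_tir_candidates(g2)
                        if (c.start, c.end) == (out_rec.start, out_rec.end))
            for n in detect_nested(cand, g2):
                assert n.inner.start >= cand.tir.tir_length
                assert n.inner.end <= cand.length - cand.tir.tir_length


@pytest.fixture(scope="module")
def locus(clean_family):
    _, _, copies = clean_family
    element = copies[0].seq
    fl = generate_background(400, 0.65, seed=321).residues
    fr = generate_background(400, 0.65, seed=322).residues
    ref = fl + "TA" + element + "TA" + fr
    span = (len(fl) + 2, len(fl) + 2 + len(element))
    return element, fl, fr, ref, span


class TestClassifier:
    def test_reference_classifies_occupied(self, locus):
        element, fl, fr, ref, span = locus
        v = classify_locus_variant(ref, span, GenomicSequence("a", ref))
        assert v.variant_class == "occupied"

    def test_reconstructed_empty_site(self, locus):
        element, fl, fr, ref, span = locus
        empty = reconstruct_preinsertion(ref, *span)
        v = classify_locus_variant(ref, span, GenomicSequence("a", empty))
        assert v.variant_class == "empty"

    def test_population_recovery(self, locus):
        element, fl, fr, ref, span = locus
        freqs = {"occupied": 0.3, "empty": 0.25, "footprint": 0.15,
                 "internal_deletion": 0.15, "clustered": 0.15}
        pop = simulate_locus_population((fl, fr), element, freqs, 100,
                                        seed=323)
        ok = sum(1 for a in pop
                 if classify_locus_variant(ref, span, a.haplotype)
                 .variant_class == a.true_class)
        assert ok / len(pop) >= 0.95

    def test_wrong_locus_is_an_error(self, locus):
        element, fl, fr, ref, span = locus
        other = generate_background(900, 0.65, seed=324)
        with pytest.raises(LocusAnchorError):
            classify_locus_variant(ref, span, other)


class TestInsilicoPCR:
    def test_no_binding_sites(self):
        t = GenomicSequence("t", "AT" * 200)
        p = PrimerSpec("p", "GGGCCCGGGCCCGGG")
        assert insilico_pcr(t, p) == []

    def test_occupied_vs_empty_length_difference(self, clean_family):
        _, _, copies = clean_family
        element = copies[0].seq
        fl = generate_background(300, 0.65, seed=331).residues
        fr = generate_background(300, 0.65, seed=332).residues
        occupied = GenomicSequence("o", fl + "TA" + element + "TA" + fr)
        empty = GenomicSequence("e", fl + "TA" + fr)
        fwd = PrimerSpec("F", fl[200:220])
        rev = PrimerSpec("R", revcomp(fr[80:100]))
        amp_o = insilico_pcr(occupied, fwd, rev)
        amp_e = insilico_pcr(empty, fwd, rev)
        assert len(amp_o) == len(amp_e) == 1
        assert amp_o[0].length - amp_e[0].length == len(element) + 2

    def test_single_primer_tir_mode_spans_element(self):
        # element whose TIRs embed the primer geometry: primer binds the
        # left TIR forward and the right TIR (its reverse complement) reverse
        primer = "TACTCCCTCCGTCCCACC"
        core = primer[2:]  # starts with CTCCCT
        interior = "ATTTAGCAATTGAAATTCGAGTTAAACCTTATTAGC"
        element = core + interior + revcomp(core)
        fl = generate_background(120, 0.65, seed=333).residues
        fr = generate_background(120, 0.65, seed=334).residues
        template = GenomicSequence("t", fl + "TA" + element + "TA" + fr)
        amps = insilico_pcr(template, PrimerSpec("tir", primer),
                            params=PCRParams(max_mismatch=2))
        lengths = {a.length for a in amps}
        # the primer's 5' TA sits on the TSD, so the product spans the
        # element plus both TA copies
        assert len(element) + 4 in lengths

    def test_strand_symmetry(self, clean_family):
        _, _, copies = clean_family
        element = copies[0].seq
        fl = generate_background(200, 0.65, seed=335).residues
        fr = generate_background(200, 0.65, seed=336).residues
        t = GenomicSequence("t", fl + "TA" + element + "TA" + fr)
        rc = GenomicSequence("rc", revcomp(t.residues))
        fwd = PrimerSpec("F", fl[100:120])
        rev = PrimerSpec("R", revcomp(fr[60:80]))
        la = sorted(a.length for a in insilico_pcr(t, fwd, rev))
        lb = sorted(a.length for a in insilico_pcr(rc, fwd, rev))
        assert la == lb


class TestPolymorphismReport:
    def test_monomorphic_locus(self):
        variants = [LocusVariant(f"a{i}", "occupied", 900) for i in range(5)]
        rep = polymorphism_report({"L1": variants})
        row = rep.iloc[0]
        assert not row["polymorphic"] and row["insertion_frequency"] == 1.0

    def test_insertion_frequency(self):
        variants = ([LocusVariant(f"a{i}", "occupied", 900) for i in range(3)]
                    + [LocusVariant(f"b{i}", "empty", 600) for i in range(2)])
        rep = polymorphism_report({"L1": variants})
        row = rep.iloc[0]
        assert row["insertion_frequency"] == pytest.approx(0.6)
        assert row["polymorphic"]

    def test_class_counts_sum_to_n(self):
        variants = ([LocusVariant("a", "occupied", 900)]
                    + [LocusVariant("b", "footprint", 610)]
                    + [LocusVariant("c", "empty", 600)])
        rep = polymorphism_report({"L1": variants})
        row = rep.iloc[0]
        total = sum(row[c] for c in ("occupied", "empty", "footprint",
                                     "internal_deletion", "clustered",
                                     "complex"))
        assert total == row["n"] == 3

    def test_requires_a_locus(self):
        with pytest.raises(ValueError):
            polymorphism_report({})
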