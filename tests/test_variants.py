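import numpy as np
import pytest

from gofamcat.simulate import VariantTruth, make_gene, mutate, plant_variants
from gofamcat.variants import (
    GeneModel,
    assign_genome_origin,
    compare_pair,
    compare_structures,
    detect_indels,
    detect_ltr_insertion,
    find_ssr,
    map_cds_to_genome,
    ssr_difference,
)

from conftest import random_dna


class TestGeneModel:
    def test_cds_is_exon_concatenation(self):
        g = make_gene(seed=0)
        assert g.cds == "".join(g.genomic[s:e] for s, e in g.exons)

    def test_gt_ag_enforced(self):
        with pytest.raises(ValueError, match="GT..AG"):
            GeneModel(
                gene_id="x",
                genomic="ATGAAA" + "CC" + "A" * 40 + "AG" + "TTTTAA",
                exons=[(0, 6), (50, 56)],
            )

    def test_short_intron_rejected(self):
        with pytest.raises(ValueError, match="min_intron"):
            GeneModel(
                gene_id="x",
                genomic="ATGAAA" + "GT" + "A" * 16 + "AG" + "TTTTAA",
                exons=[(0, 6), (26, 32)],
            )


class TestMapCdsToGenome:
    def test_intronless_gene_single_exon(self, rng):
        cds = random_dna(rng, 120)
        model = map_cds_to_genome(cds, cds)
        assert model.exons == [(0, 120)]

    def test_planted_three_exon_gene_recovered(self):
        g = make_gene(cds_length=300, n_introns=2, seed=2)
        model = map_cds_to_genome(g.cds, g.genomic)
        assert model.exons == g.exons

    def test_seven_exon_gene_recovered(self):
        g = make_gene(cds_length=630, n_introns=6, seed=9)
        model = map_cds_to_genome(g.cds, g.genomic)
        assert model.exons == g.exons
        assert model.cds == g.cds

    def test_short_intron_not_used(self, rng):
        exon1, exon2 = random_dna(rng, 60), random_dna(rng, 60)
        genomic = exon1 + "GT" + random_dna(rng, 16) + "AG" + exon2
        with pytest.raises(ValueError, match="best partial"):
            map_cds_to_genome(exon1 + exon2, genomic, min_intron=40)

    def test_error_reports_best_partial_chain(self, rng):
        cds = random_dna(rng, 100)
        genomic = cds[:50] + random_dna(rng, 200)
        with pytest.raises(ValueError, match=r"\d+/100 CDS bases"):
            map_cds_to_genome(cds, genomic)


class TestGenomeOrigin:
    def test_identical_to_a(self, rng):
        a = random_dna(rng, 200)
        d = mutate(a, 0.05, 3, moltype="dna")
        out = assign_genome_origin(a, a, d)
        assert out.origin == "A"
        assert out.dist_a == 0
        assert out.margin == pytest.approx(out.dist_d)

    def test_equidistant_is_ambiguous(self, rng):
        a = random_dna(rng, 200)
        out = assign_genome_origin(a, a, a)
        assert out.origin == "ambiguous"

    def test_tetraploid_copies_assigned_correctly(self):
        correct = 0
        for seed in range(10):
            base = random_dna(np.random.default_rng(seed), 300)
            diploid_a = mutate(base, 0.025, seed * 2 + 1, moltype="dna")
            diploid_d = mutate(base, 0.025, seed * 2 + 2, moltype="dna")
            tetra_a = mutate(diploid_a, 0.01, seed + 100, moltype="dna")
            out = assign_genome_origin(tetra_a, diploid_a, diploid_d)
            correct += out.origin == "A"
        assert correct == 10


class TestIndels:
    def test_identical_sequences_no_indels(self, rng):
        cds = random_dna(rng, 300)
        assert detect_indels(cds, cds) == []

    def test_four_nt_deletion_is_frameshift(self, rng):
        a = random_dna(rng, 200)
        b = a[:100] + a[104:]
        (ind,) = detect_indels(a, b)
        assert ind.length == 4
        assert not ind.in_frame
        assert ind.deleted_in == "b"

    def test_antisymmetry(self, rng):
        a = random_dna(rng, 200)
        b = a[:80] + a[95:]
        (fwd,) = detect_indels(a, b)
        (rev,) = detect_indels(b, a)
        assert fwd.length == rev.length == 15
        assert {fwd.deleted_in, rev.deleted_in} == {"a", "b"}
        assert (fwd.position, fwd.position_other) == (rev.position_other, rev.position)


class TestSSR:
    def test_direct_count(self):
        runs = find_ssr("AA" + "GAA" * 7 + "TT", "GAA")
        assert runs == [(2, 7)]

    def test_below_min_copies_empty(self):
        assert find_ssr("GAAGAA", "GAA", min_copies=4) == []

    def test_empty_unit_raises(self):
        with pytest.raises(ValueError):
            find_ssr("ACGT", "")

    def test_nine_versus_thirteen_is_twelve_nt(self):
        a = "CCTT" + "GAA" * 9 + "GGCC"
        b = "CCTT" + "GAA" * 13 + "GGCC"
        diff = ssr_difference(a, b, "GAA")
        assert (diff.copies_a, diff.copies_b) == (9, 13)
        assert diff.length_difference_nt == -12


class TestLtrInsertion:
    def test_identical_introns_none(self, rng):
        intron = random_dna(rng, 800)
        assert detect_ltr_insertion(intron, intron) is None

    def test_insertion_without_repeats_reported_without_tr(self, rng):
        intron = random_dna(rng, 600)
        element = random_dna(rng, 800)
        bigger = intron[:300] + element + intron[300:]
        rec = detect_ltr_insertion(intron, bigger)
        assert rec is not None
        assert rec.host == "b"
        assert rec.length == 800
        assert rec.terminal_repeat is None

    def test_terminal_repeats_recovered_exactly(self, rng):
        intron = random_dna(rng, 500)
        tr = random_dna(rng, 300)
        element = tr + random_dna(rng, 1400) + tr
        bigger = intron[:200] + element + intron[200:]
        rec = detect_ltr_insertion(intron, bigger)
        assert rec.length == 2000
        assert rec.terminal_repeat == (300, 1.0)

    def test_small_difference_below_gate_ignored(self, rng):
        intron = random_dna(rng, 600)
        other = intron[:300] + random_dna(rng, 100) + intron[300:]
        assert detect_ltr_insertion(intron, other) is None


class TestStructures:
    def test_intron_loss_by_exon_fusion(self):
        g = make_gene(cds_length=630, n_introns=6, seed=13)
        exons = [g.genomic[s:e] for s, e in g.exons]
        introns = [g.genomic[s:e] for s, e in g.introns]
        # fuse exon4+exon5 in the second ortholog: intron 4 lost
        fused_parts = []
        fused_exons = []
        offset = 0
        keep = [0, 1, 2, 4, 5]  # intron indices kept (0-based, drop 3)
        merged = exons[:3] + [exons[3] + exons[4]] + exons[5:]
        kept_introns = introns[:3] + introns[4:]
        for k, ex in enumerate(merged):
            fused_parts.append(ex)
            fused_exons.append((offset, offset + len(ex)))
            offset += len(ex)
            if k < len(kept_introns):
                fused_parts.append(kept_introns[k])
                offset += len(kept_introns[k])
        fused = GeneModel(
            gene_id="fused", genomic="".join(fused_parts), exons=fused_exons
        )
        diff = compare_structures([g, fused])
        assert diff["exon_counts"] == {"gene": 7, "fused": 6}
        assert diff["lost_introns"] == {4: ["fused"]}

    def test_identical_structures_empty_diff(self):
        g = make_gene(seed=3)
        h = GeneModel(gene_id="other", genomic=g.genomic, exons=list(g.exons))
        assert compare_structures([g, h])["lost_introns"] == {}

    def test_single_model_raises(self):
        with pytest.raises(ValueError):
            compare_structures([make_gene(seed=1)])


class TestComparePair:
    def test_full_report_on_planted_pair(self):
        gene = make_gene(cds_length=630, n_introns=6, seed=21)
        spec = VariantTruth(
            deletion=(6, 20, 15), ssr=("GAA", 9, 13, 6), insertion=(4, 2000, 300)
        )
        a, b, spec = plant_variants(gene, spec, seed=21)
        report = compare_pair(a, b)
        dels = [i for i in report.indels if i.length == 15 and i.deleted_in == "b"]
        assert len(dels) == 1
        assert dels[0].in_frame and dels[0].exon == 6
        (ssr,) = report.ssr
        assert (ssr.copies_a, ssr.copies_b, ssr.exon) == (9, 13, 6)
        (ins,) = report.insertions
        assert (ins.intron, ins.length, ins.terminal_repeat) == (4, 2000, (300, 1.0))
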