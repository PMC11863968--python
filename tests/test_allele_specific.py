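"""Pseudo-genome construction and allele-specific design."""

import pytest

from guidex.allele_specific import (
    AlleleError,
    AlleleSpecificRecord,
    HighConfidenceConfig,
    Variant,
    annotate_genes,
    apply_variants,
    classify_discrimination,
    design_allele_specific,
    high_confidence_filter,
    read_vcf,
    write_vcf,
)
from guidex.bruteforce import scan_offtargets
from guidex.fm_index import build_index
from guidex.genome_io import Annotation, Genome, GenomicInterval
from guidex.guide_database import (
    DatabaseParams,
    GuideRecord,
    build_database,
    enumerate_candidates,
)
from guidex.offtarget_search import PamSpec
from guidex.scoring import EfficiencyModel
from guidex.synthetic_fixtures import random_genome, simulate_diploid


class TestApplyVariants:
    def test_snp(self):
        g = Genome({"c": "AAAAAAAAAA"})
        pseudo, cmap = apply_variants(g, [Variant("c", 5, "A", "G")])
        assert pseudo["c"] == "AAAAAGAAAA"
        assert cmap.map_position("c", 7) == 7

    def test_insertion_shifts_downstream(self):
        g = Genome({"c": "AAAATTTT"})
        pseudo, cmap = apply_variants(g, [Variant("c", 3, "A", "ACC")])
        assert pseudo["c"] == "AAAACCTTTT"
        assert cmap.map_position("c", 2) == 2
        assert cmap.map_position("c", 4) == 6  # +2 after the insertion

    def test_deletion_marks_interval_unmappable(self):
        g = Genome({"c": "AACCGGTT"})
        pseudo, cmap = apply_variants(g, [Variant("c", 1, "ACC", "A")])
        assert pseudo["c"] == "AAGGTT"
        assert cmap.map_position("c", 2) is None
        assert cmap.map_position("c", 3) is None
        assert cmap.map_position("c", 4) == 2

    def test_ref_mismatch_rejected(self):
        g = Genome({"c": "AAAA"})
        with pytest.raises(AlleleError, match="ref mismatch"):
            apply_variants(g, [Variant("c", 1, "G", "T")])

    def test_overlap_rejected(self):
        g = Genome({"c": "AACCGGTT"})
        with pytest.raises(AlleleError, match="overlap"):
            apply_variants(
                g, [Variant("c", 1, "ACC", "A"), Variant("c", 2, "C", "T")]
            )

    def test_nonvariant_bases_map_identically(self):
        g = random_genome(3_000, seed=51)
        variants, pseudo = simulate_diploid(g, 0.01, 0.001, seed=52)
        spans = {(v.sequence, v.position, v.end) for v in variants}
        cmapped = apply_variants(g, variants)[1]
        name = g.names[0]
        for pos in range(0, g.lengths[name], 97):
            if any(s <= pos < e for _, s, e in spans):
                continue
            mapped = cmapped.map_position(name, pos)
            assert mapped is not None
            assert pseudo[name][mapped] == g[name][pos]


class TestVcfIO:
    def test_roundtrip(self, tmp_path):
        g = random_genome(2_000, seed=53)
        variants, _ = simulate_diploid(g, 0.01, 0.002, seed=54, het_fraction=0.3)
        p = tmp_path / "v.vcf"
        write_vcf(variants, g, str(p))
        back = read_vcf(str(p))
        assert [(v.sequence, v.position, v.ref, v.alt, v.zygosity) for v in back] == [
            (v.sequence, v.position, v.ref, v.alt, v.zygosity) for v in variants
        ]


@pytest.fixture(scope="module")
def diploid(cfd_table):
    genome_a = random_genome(15_000, seed=55)
    variants, genome_b = simulate_diploid(genome_a, 0.004, 0.0004, seed=56)
    idx_a, idx_b = build_index(genome_a), build_index(genome_b)
    model = EfficiencyModel.seeded_hash(3)
    params = DatabaseParams()
    db_a = build_database(idx_a, enumerate_candidates(genome_a), params, cfd_table,
                          model, genome=genome_a)
    db_b = build_database(idx_b, enumerate_candidates(genome_b), params, cfd_table,
                          model, genome=genome_b)
    a_spec, b_spec = design_allele_specific(db_a, idx_b, db_b, idx_a)
    return genome_a, genome_b, variants, a_spec, b_spec


class TestDesign:
    def test_cross_exclusion_sound(self, diploid):
        genome_a, genome_b, _, a_spec, b_spec = diploid
        for rec in a_spec:
            assert scan_offtargets(genome_b, rec.record.spacer, PamSpec(), 0) == []
        for rec in b_spec:
            assert scan_offtargets(genome_a, rec.record.spacer, PamSpec(), 0) == []

    def test_variant_free_guides_excluded(self, diploid):
        # an allele-specific set cannot contain a guide whose spacer+PAM
        # matches both genomes perfectly
        genome_a, genome_b, _, a_spec, _ = diploid
        assert all(
            scan_offtargets(genome_b, r.record.spacer, PamSpec(), 0) == []
            for r in a_spec
        )

    def test_label_swap_symmetry(self, diploid, cfd_table):
        genome_a, genome_b, variants, a_spec, b_spec = diploid
        idx_a, idx_b = build_index(genome_a), build_index(genome_b)
        model = EfficiencyModel.seeded_hash(3)
        params = DatabaseParams()
        db_a = build_database(idx_a, enumerate_candidates(genome_a), params, cfd_table,
                              model, genome=genome_a)
        db_b = build_database(idx_b, enumerate_candidates(genome_b), params, cfd_table,
                              model, genome=genome_b)
        swapped_a, swapped_b = design_allele_specific(db_b, idx_a, db_a, idx_b)
        assert [r.record.guide_id for r in swapped_a] == [
            r.record.guide_id for r in b_spec
        ]
        assert [r.record.guide_id for r in swapped_b] == [
            r.record.guide_id for r in a_spec
        ]

    def test_planted_snp_makes_guide_allele_specific(self, cfd_table):
        genome_a = random_genome(6_000, seed=57)
        name = genome_a.names[0]
        # choose a guide locus with an AGG PAM planted on the reference
        seq = list(genome_a[name])
        spacer = "ACGTACGGTTCAGCTAAGCT"
        seq[1_000:1_023] = list(spacer + "AGG")
        genome_a = Genome({name: "".join(seq)})
        snp = Variant(name, 1_010, spacer[10], "G" if spacer[10] != "G" else "C")
        genome_b, _ = apply_variants(genome_a, [snp])
        idx_a, idx_b = build_index(genome_a), build_index(genome_b)
        params = DatabaseParams()
        db_a = build_database(idx_a, enumerate_candidates(genome_a), params,
                              cfd_table, genome=genome_a)
        db_b = build_database(idx_b, enumerate_candidates(genome_b), params,
                              cfd_table, genome=genome_b)
        a_spec, b_spec = design_allele_specific(db_a, idx_b, db_b, idx_a)
        assert spacer in {r.record.spacer for r in a_spec}
        mutated = spacer[:10] + snp.alt + spacer[11:]
        assert mutated in {r.record.spacer for r in b_spec}


class TestClassification:
    def _rec(self, start=100, end=120, strand="+"):
        return GuideRecord(
            guide_id="g", sequence="c", start=start, end=end, strand=strand,
            spacer="A" * 20, pam="AGG",
        )

    def test_pam_variant_beats_protospacer(self):
        rec = self._rec()
        cat, hits = classify_discrimination(
            rec, [Variant("c", 121, "A", "G"), Variant("c", 110, "A", "G")]
        )
        assert cat == "pam_variant" and len(hits) == 1

    def test_protospacer_variant(self):
        cat, _ = classify_discrimination(self._rec(), [Variant("c", 110, "A", "G")])
        assert cat == "protospacer_variant"

    def test_minus_strand_pam_window(self):
        rec = self._rec(strand="-")
        cat, _ = classify_discrimination(rec, [Variant("c", 98, "A", "G")])
        assert cat == "pam_variant"

    def test_structural_fallback(self):
        cat, hits = classify_discrimination(self._rec(), [Variant("c", 500, "A", "G")])
        assert cat == "structural" and hits == []


def _as_rec(gid, start=100, eff=1.0, a=None, b=None, het=False, strand="+"):
    rec = GuideRecord(
        guide_id=gid, sequence="c", start=start, end=start + 20, strand=strand,
        spacer="A" * 20, pam="AGG", efficiency=eff,
    )
    out = AlleleSpecificRecord(
        record=rec, target_allele="A",
        offtargets_in_A=a or {2: 0, 3: 0}, offtargets_in_B=b or {2: 0, 3: 0},
    )
    if het:
        out.overlapping_variants = [Variant("c", start + 5, "A", "G", zygosity="het")]
    return out


class TestHighConfidenceFilter:
    def test_each_stage_removes_planted_violator(self):
        records = [
            _as_rec("clean1", 100),
            _as_rec("clean2", 400),
            _as_rec("het", 700, het=True),
            _as_rec("two_mm", 1_000, b={2: 1, 3: 0}),
            _as_rec("many_3mm", 1_300, a={2: 0, 3: 4}),
            _as_rec("weak_eff", 1_600, eff=0.1),
            _as_rec("near_repeat", 1_900),
        ]
        config = HighConfidenceConfig(
            repeats=[GenomicInterval("c", 2_000, 2_100, "+", "rpt")]
        )
        survivors, report = high_confidence_filter(records, config)
        assert {r.guide_id for r in survivors} == {"A|clean1", "A|clean2"}
        assert report.counts == [7, 6, 5, 4, 3, 2]

    def test_repeat_distance_rule(self):
        # cut site of [1900,1920)+ is 1916; repeat at 2080 is 164 bp away
        records = [_as_rec("near", 1_900), _as_rec("far", 100)]
        config = HighConfidenceConfig(
            exclude_het=False,
            repeats=[GenomicInterval("c", 2_080, 2_090, "+", "rpt")],
        )
        survivors, _ = high_confidence_filter(records, config)
        assert [r.guide_id for r in survivors] == ["A|far"]

    def test_missing_efficiency_rejected(self):
        rec = _as_rec("x")
        rec.record.efficiency = None
        with pytest.raises(AlleleError, match="efficiency"):
            high_confidence_filter([rec])


class TestAnnotateGenes:
    def test_exon_overlap_with_deterministic_tie(self):
        ann = Annotation(
            genes={
                "gB": GenomicInterval("c", 50, 300, "+", "gB"),
                "gA": GenomicInterval("c", 60, 300, "+", "gA"),
                "gC": GenomicInterval("c", 400, 600, "+", "gC"),
            },
            exons={
                "gB": [GenomicInterval("c", 100, 200, "+", "gB")],
                "gA": [GenomicInterval("c", 100, 200, "+", "gA")],
                "gC": [GenomicInterval("c", 400, 500, "+", "gC")],
            },
            cds={},
        )
        in_exon = _as_rec("hit", 100)      # cut site 116: gA and gB overlap
        intronic = _as_rec("miss", 250)    # cut site 266: no exon
        annotate_genes([in_exon, intronic], ann)
        assert in_exon.gene == "gA"  # lexicographically smallest
        assert intronic.gene is None
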