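"""Database construction, hex encoding and SAM round trips."""

import numpy as np
import pytest

from guidex.fm_index import build_index
from guidex.genome_io import Genome
from guidex.guide_database import (
    DatabaseError,
    DatabaseParams,
    build_database,
    decode_offtargets_hex,
    encode_offtargets_hex,
    enumerate_candidates,
    partition_run,
    read_sam,
    write_sam,
)
from guidex.offtarget_search import PamSpec, SearchBudget, find_perfect_sites
from guidex.scoring import EfficiencyModel
from guidex.synthetic_fixtures import PlantedSite, plant_sites, random_genome

SPACER = "ACGTACGGTTCAGCTAAGCT"


class TestEnumerateCandidates:
    def test_hand_enumeration_tiny_genome(self):
        # "AAACGGTTT": + strand window "AAA" + PAM "CGG"; - strand none for
        # length 3 (revcomp = AAACCGTTT has CGT/CCG... only NGG counts)
        g = Genome({"s": "AAACGGTTT"})
        cands = enumerate_candidates(g, PamSpec("NGG", ()), length=3)
        plus = [(c.start, c.strand, c.spacer, c.pam) for c in cands]
        assert (0, "+", "AAA", "CGG") in plus
        for c in cands:
            assert c.pam[1:] == "GG"

    def test_all_a_genome_has_no_candidates(self):
        g = Genome({"s": "A" * 100})
        assert enumerate_candidates(g) == []

    def test_cc_creates_minus_strand_candidate(self):
        g = Genome({"s": "A" * 30 + "CC" + "T" * 30})
        cands = enumerate_candidates(g, length=20)
        assert any(c.strand == "-" for c in cands)
        assert all(c.strand == "-" for c in cands)  # no GG on + strand

    def test_deterministic_sorted_order(self, small_genome):
        cands = enumerate_candidates(small_genome)
        keys = [(c.start, c.strand) for c in cands]
        assert keys == sorted(keys, key=lambda t: (t[0], t[1] == "-"))

    def test_n_windows_excluded(self):
        g = Genome({"s": "A" * 25 + "N" + "A" * 5 + "TGG" + "A" * 25})
        assert all("N" not in c.spacer for c in enumerate_candidates(g))


@pytest.fixture(scope="module")
def db_fixture(cfd_table):
    g = random_genome(12_000, seed=31)
    genome, _ = plant_sites(
        g, SPACER, PamSpec(), [PlantedSite(2_000, "+")], SearchBudget(0, 0, 0), seed=1
    )
    index = build_index(genome)
    cands = enumerate_candidates(genome)
    model = EfficiencyModel.seeded_hash(9)
    records = build_database(
        index, cands, DatabaseParams(), cfd_table, model, genome=genome
    )
    return genome, index, records


class TestBuildDatabase:
    def test_duplicated_spacer_yields_no_record(self, cfd_table):
        g = random_genome(9_000, seed=33)
        genome, _ = plant_sites(
            g, SPACER, PamSpec(),
            [PlantedSite(1_000, "+"), PlantedSite(5_000, "+")],
            SearchBudget(0, 0, 0), seed=1,
        )
        index = build_index(genome)
        cands = [c for c in enumerate_candidates(genome) if c.spacer == SPACER]
        assert len(cands) == 2
        records = build_database(index, cands, DatabaseParams(), cfd_table, genome=genome)
        assert records == []

    def test_planted_nag_offtarget_counted_at_its_distance(self, cfd_table):
        g = random_genome(9_000, seed=35)
        genome, truth = plant_sites(
            g, SPACER, PamSpec(),
            [PlantedSite(1_000, "+"), PlantedSite(5_000, "+", mismatches=2, pam="CAG")],
            SearchBudget(3, 0, 0), seed=2,
        )
        index = build_index(genome)
        cands = [c for c in enumerate_candidates(genome) if c.spacer == SPACER]
        records = build_database(index, cands, DatabaseParams(), cfd_table, genome=genome)
        assert len(records) == 1
        assert records[0].offtarget_summary[2] >= 1

    def test_empty_candidates(self, small_index, cfd_table):
        assert build_database(small_index, [], DatabaseParams(), cfd_table) == []

    def test_every_record_unique_genome_wide(self, db_fixture):
        genome, index, records = db_fixture
        rng = np.random.default_rng(0)
        sample = rng.choice(len(records), size=min(25, len(records)), replace=False)
        for i in sample:
            rec = records[int(i)]
            sites = find_perfect_sites(index, rec.spacer, PamSpec(), primary_only=True)
            assert len(sites) == 1
            assert (sites[0].sequence, sites[0].start, sites[0].strand) == (
                rec.sequence, rec.start, rec.strand,
            )

    def test_genome_index_mismatch_rejected(self, db_fixture, cfd_table):
        _, index, _ = db_fixture
        other = random_genome(3_000, seed=99)
        with pytest.raises(DatabaseError, match="not built"):
            build_database(index, [], DatabaseParams(), cfd_table, genome=other)


class TestHexEncoding:
    def test_empty_list_is_empty_string(self):
        assert encode_offtargets_hex([], {}) == ""
        assert decode_offtargets_hex("") == []

    def test_hand_computed_layout(self):
        # version byte 0x01; coord 5 strand '-': word = 5<<1|1 = 11 = 0x0b
        # little-endian over 8 bytes; distance 2
        hexstr = encode_offtargets_hex([(5, "-", 2)], {})
        assert hexstr == "01" + "0b00000000000000" + "02"

    def test_roundtrip_random_triples(self):
        rng = np.random.default_rng(41)
        triples = [
            (int(rng.integers(0, 2**40)), "+-"[int(rng.integers(0, 2))], int(rng.integers(0, 8)))
            for _ in range(1_000)
        ]
        assert decode_offtargets_hex(encode_offtargets_hex(triples, {})) == triples

    @pytest.mark.parametrize("bad", ["0", "zz", "01ab", "0201"])
    def test_malformed_hex_rejected(self, bad):
        with pytest.raises(DatabaseError):
            decode_offtargets_hex(bad)


class TestSam:
    def test_roundtrip(self, tmp_path, db_fixture):
        genome, index, records = db_fixture
        path = tmp_path / "db.sam"
        write_sam(records, genome, str(path))
        back = read_sam(str(path))
        assert len(back) == len(records)
        offsets = dict(genome.offsets)
        for rec, b in zip(records, back):
            assert (b.guide_id, b.sequence, b.start, b.end, b.strand) == (
                rec.guide_id, rec.sequence, rec.start, rec.end, rec.strand,
            )
            assert b.spacer == rec.spacer and b.pam == rec.pam
            assert b.specificity == pytest.approx(rec.specificity, abs=1e-5)
            assert b.efficiency == pytest.approx(rec.efficiency, abs=1e-5)
            assert b.offtarget_summary == rec.offtarget_summary
            want = [
                (offsets[o.sequence] + o.start, o.strand, o.distance)
                for o in rec.offtargets
            ]
            got = [
                (offsets[o.sequence] + o.start, o.strand, o.distance)
                for o in b.offtargets
            ]
            assert got == want

    def test_coordinates_are_one_based_and_flagged(self, tmp_path, db_fixture):
        genome, _, records = db_fixture
        path = tmp_path / "db.sam"
        write_sam(records[:20], genome, str(path))
        lines = [l for l in path.read_text().splitlines() if not l.startswith("@")]
        for rec, line in zip(records[:20], lines):
            f = line.split("\t")
            assert int(f[3]) == rec.start + 1
            assert int(f[1]) == (16 if rec.strand == "-" else 0)

    def test_unknown_sequence_rejected(self, tmp_path, db_fixture):
        genome, _, records = db_fixture
        import dataclasses

        bad = dataclasses.replace(records[0], sequence="chrMissing")
        with pytest.raises(DatabaseError, match="unknown sequence"):
            write_sam([bad], genome, str(tmp_path / "x.sam"))

    def test_header_valid_for_pysam(self, tmp_path, db_fixture):
        import pysam

        genome, _, records = db_fixture
        path = tmp_path / "db.sam"
        write_sam(records, genome, str(path))
        with pysam.AlignmentFile(str(path), "r") as sam:
            assert list(sam.references) == genome.names


class TestPartitioning:
    def test_partition_equivalence(self, db_fixture, cfd_table):
        genome, index, single = db_fixture
        cands = enumerate_candidates(genome)
        model = EfficiencyModel.seeded_hash(9)

        def worker(part):
            return build_database(index, part, DatabaseParams(), cfd_table, model, genome=genome)

        seq_order = {name: i for i, name in enumerate(genome.names)}
        for parts in (1, 7, len(cands) + 5):
            merged = partition_run(cands, parts, worker, seq_order)
            assert [(r.guide_id, r.offtarget_summary) for r in merged] == [
                (r.guide_id, r.offtarget_summary) for r in single
            ]

    def test_summary_totals_invariant_under_partitioning(self, db_fixture, cfd_table):
        genome, index, single = db_fixture
        totals = {}
        for r in single:
            for d, c in r.offtarget_summary.items():
                totals[d] = totals.get(d, 0) + c
        cands = enumerate_candidates(genome)

        def worker(part):
            return build_database(index, part, DatabaseParams(), cfd_table, genome=genome)

        seq_order = {name: i for i, name in enumerate(genome.names)}
        merged = partition_run(cands, 5, worker, seq_order)
        totals5 = {}
        for r in merged:
            for d, c in r.offtarget_summary.items():
                totals5[d] = totals5.get(d, 0) + c
        assert totals5 == totals
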