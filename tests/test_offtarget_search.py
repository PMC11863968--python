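"""Off-target enumeration vs the brute-force oracles."""

import pytest

from guidex.bruteforce import (
    hamming_window_count,
    scan_offtargets,
    scan_offtargets_bulged,
)
from guidex.fm_index import build_index
from guidex.genome_io import Genome, reverse_complement
from guidex.offtarget_search import (
    GuideQuery,
    PamSpec,
    SearchBudget,
    SearchError,
    cut_site,
    enumerate_offtargets,
    expand_pam,
    find_perfect_sites,
    hamming_occurrences,
)
from guidex.synthetic_fixtures import PlantedSite, plant_sites, random_genome

SPACER = "ACGTACGGTTCAGCTAAGCT"
PAM = PamSpec()


def locus_key(o):
    return (o.sequence, o.strand, o.pam_start, o.distance)


def align_key(o):
    return (o.sequence, o.strand, o.pam_start, o.distance, o.rna_bulges, o.dna_bulges)


@pytest.fixture(scope="module")
def planted():
    g = random_genome(50_000, seed=21)
    placements = [
        PlantedSite(1_000, "+"),
        PlantedSite(2_000, "+", mismatches=2),
        PlantedSite(3_000, "-", mismatches=1),
        PlantedSite(4_000, "-", mismatches=3),
        PlantedSite(5_000, "+", mismatches=1, pam="TAG"),
    ]
    genome, truth = plant_sites(g, SPACER, PAM, placements, SearchBudget(3, 0, 0), seed=22)
    return genome, build_index(genome), truth


class TestExpandPam:
    @pytest.mark.parametrize("motif,n", [("NGG", 4), ("NRG", 8), ("GG", 1), ("NNN", 64)])
    def test_degeneracy_product(self, motif, n):
        concrete = expand_pam(motif)
        assert len(concrete) == n == len(set(concrete))

    def test_ngg_expansions(self):
        assert set(expand_pam("NGG")) == {"AGG", "CGG", "GGG", "TGG"}

    def test_invalid_code_rejected(self):
        with pytest.raises(SearchError):
            expand_pam("NXG")


class TestMismatchSearch:
    def test_planted_truth_recovered(self, planted):
        genome, index, truth = planted
        hits = enumerate_offtargets(
            index, GuideQuery(SPACER), SearchBudget(3, 0, 0), genome=genome,
            include_on_target=True,
        )
        assert sorted(map(locus_key, hits)) == sorted(map(locus_key, truth))

    def test_budget_monotonicity(self, planted):
        genome, index, _ = planted
        previous = set()
        for k in range(5):
            hits = {
                locus_key(o)
                for o in enumerate_offtargets(
                    index, GuideQuery(SPACER), SearchBudget(k, 0, 0),
                    genome=genome, include_on_target=True,
                )
            }
            assert previous <= hits
            previous = hits

    def test_declared_on_target_excluded(self, planted):
        genome, index, truth = planted
        exact = next(t for t in truth if t.distance == 0)
        query = GuideQuery(
            SPACER, PAM, declared_on_target=(exact.sequence, exact.start, exact.strand)
        )
        hits = enumerate_offtargets(index, query, SearchBudget(3, 0, 0), genome=genome)
        assert locus_key(exact) not in {locus_key(o) for o in hits}
        assert len(hits) == len(truth) - 1

    def test_mismatch_reporting_is_one_based_from_5prime(self, planted):
        genome, index, _ = planted
        hits = enumerate_offtargets(
            index, GuideQuery(SPACER), SearchBudget(3, 0, 0), genome=genome,
            include_on_target=True,
        )
        for o in hits:
            for pos, sb, gb in o.mismatches:
                assert 1 <= pos <= 20
                assert SPACER[pos - 1] == sb != gb
                assert o.matched_protospacer[pos - 1] == gb

    def test_strand_symmetry(self):
        """Searching s on G mirrors searching revcomp(s) on revcomp(G)."""
        g = random_genome(8_000, seed=23)
        g_rc = Genome({"chr1": reverse_complement(g["chr1"])})
        n = g.lengths["chr1"]
        fwd = scan_offtargets(g, SPACER, PAM, 3)
        # a site of s on G at [a,b) strand z corresponds to a site of s on
        # revcomp(G) at [n-b, n-a) on the opposite strand
        idx = build_index(g_rc)
        rev = enumerate_offtargets(
            idx, GuideQuery(SPACER), SearchBudget(3, 0, 0), genome=g_rc,
            include_on_target=True,
        )
        mirrored = {
            (n - o.end, n - o.start, "-" if o.strand == "+" else "+", o.distance)
            for o in rev
        }
        assert {(o.start, o.end, o.strand, o.distance) for o in fwd} == mirrored


class TestLegacySemantics:
    def test_wildcard_is_superset_with_strict_inclusion(self, planted):
        genome, index, _ = planted
        # the planted TAG site has 1 spacer mismatch: at k=1 the legacy
        # semantics (alternative PAM costs one mismatch) must drop it
        for k in range(4):
            wild = {
                locus_key(o)
                for o in enumerate_offtargets(
                    index, GuideQuery(SPACER), SearchBudget(k, 0, 0),
                    genome=genome, include_on_target=True,
                )
            }
            legacy = {
                locus_key(o)
                for o in enumerate_offtargets(
                    index, GuideQuery(SPACER), SearchBudget(k, 0, 0),
                    genome=genome, include_on_target=True,
                    legacy_pam_as_mismatch=True,
                )
            }
            assert legacy <= wild
            if k == 1:
                assert legacy < wild

    def test_legacy_matches_oracle(self, planted):
        genome, index, _ = planted
        legacy = enumerate_offtargets(
            index, GuideQuery(SPACER), SearchBudget(2, 0, 0), genome=genome,
            include_on_target=True, legacy_pam_as_mismatch=True,
        )
        oracle = scan_offtargets(genome, SPACER, PAM, 2, legacy_pam_as_mismatch=True)
        assert sorted(map(locus_key, legacy)) == sorted(map(locus_key, oracle))


@pytest.fixture(scope="module")
def bulge_fixture():
    g = random_genome(8_000, seed=25)
    placements = [
        PlantedSite(500, "+"),
        PlantedSite(1_500, "+", rna_bulge_at=7),
        PlantedSite(2_500, "-", dna_bulge=(9, "A")),
        # the capability distinguishing this engine: one site carrying
        # BOTH a DNA and an RNA bulge
        PlantedSite(3_500, "+", mismatches=1, rna_bulge_at=5, dna_bulge=(12, "G")),
        PlantedSite(4_500, "-", mismatches=2, rna_bulge_at=11),
    ]
    genome, truth = plant_sites(
        g, SPACER, PAM, placements, SearchBudget(2, 1, 1), seed=26
    )
    return genome, build_index(genome), truth


class TestBulgedSearch:
    def test_planted_bulges_recovered(self, bulge_fixture):
        genome, index, truth = bulge_fixture
        hits = enumerate_offtargets(
            index, GuideQuery(SPACER), SearchBudget(2, 1, 1), genome=genome,
            include_on_target=True,
        )
        assert sorted(map(align_key, hits)) == sorted(map(align_key, truth))
        both = [h for h in hits if h.rna_bulges and h.dna_bulges]
        assert both, "site with both bulge kinds must be found"

    def test_bulge_budget_monotonicity(self, bulge_fixture):
        genome, index, _ = bulge_fixture
        small = {
            o.locus()
            for o in enumerate_offtargets(
                index, GuideQuery(SPACER), SearchBudget(1, 1, 0), genome=genome,
                include_on_target=True,
            )
        }
        large = {
            o.locus()
            for o in enumerate_offtargets(
                index, GuideQuery(SPACER), SearchBudget(2, 1, 1), genome=genome,
                include_on_target=True,
            )
        }
        assert small <= large

    def test_each_locus_reported_once(self, bulge_fixture):
        genome, index, _ = bulge_fixture
        hits = enumerate_offtargets(
            index, GuideQuery(SPACER), SearchBudget(2, 1, 1), genome=genome,
            include_on_target=True,
        )
        loci = [h.locus() for h in hits]
        assert len(loci) == len(set(loci))


class TestPerfectSites:
    def test_unique_duplicate_and_no_pam(self):
        g = random_genome(9_000, seed=27)
        genome, _ = plant_sites(
            g, SPACER, PAM, [PlantedSite(1_000, "+")], SearchBudget(0, 0, 0), seed=1
        )
        index = build_index(genome)
        assert len(find_perfect_sites(index, SPACER, PAM)) == 1

        dup, _ = plant_sites(
            g, SPACER, PAM, [PlantedSite(1_000, "+"), PlantedSite(4_000, "-")],
            SearchBudget(0, 0, 0), seed=1,
        )
        assert len(find_perfect_sites(build_index(dup), SPACER, PAM)) == 2

        # spacer present but followed by TTT: no PAM, no site
        seq = list(random_genome(9_000, seed=28)["chr1"])
        seq[1_000 : 1_023] = list(SPACER + "TTT")
        nopam = Genome({"chr1": "".join(seq)})
        assert find_perfect_sites(build_index(nopam), SPACER, PAM) == []


class TestHammingOccurrences:
    def test_matches_naive_scan(self, small_genome, small_index):
        sub = small_genome["chr1"][700:720]
        for mm in (0, 1, 3):
            assert hamming_occurrences(small_index, sub, mm) == hamming_window_count(
                small_genome, sub, mm
            )
        assert hamming_occurrences(small_index, sub, 0) >= 1

    def test_saturating_radius_counts_all_windows(self, small_genome, small_index):
        spacer = "ACGT" * 5
        n_windows = 2 * (small_genome.lengths["chr1"] - 19)
        assert hamming_occurrences(small_index, spacer, 20) == n_windows


class TestCutSite:
    def test_plus_strand(self):
        site = _site("chr1", 100, 120, "+")
        assert cut_site(site) == ("chr1", 116)

    def test_minus_strand(self):
        site = _site("chr1", 100, 120, "-")
        assert cut_site(site) == ("chr1", 103)

    def test_five_prime_pam_undefined(self):
        with pytest.raises(SearchError, match="undefined"):
            cut_site(_site("chr1", 100, 120, "+"), pam_side="5prime")


def _site(seq, start, end, strand):
    from guidex.offtarget_search import OffTarget

    return OffTarget(
        sequence=seq, start=start, end=end, strand=strand,
        matched_protospacer="A" * (end - start), matched_pam="AGG", mismatches=[],
    )
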