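"""Gene-targeting library construction.

Filter cascade (applied in this order, each stage reported):

1. drop guides with any additional 0- or 1-mismatch genomic occurrence
   (primary or alternative PAM, matching the database's occurrence scope);
2. keep guides whose cut site lies within a CDS;
3. cutting efficiency >= 0.25;
4. specificity >= 0.20;
5. spacer G+C within [0.20, 0.80] (inclusive bounds survive; the spacer
   alone is scored, excluding the PAM);
6. no monopolymer run longer than 3.

Per gene, up to six guides are kept, ranked by
``Score(g) = min{Spec(g), Spec(g'), 1.25 * Efficiency(g)}`` where g' is
the guide with its 5' nucleotide replaced by G (a common synthesis
substitution); Spec(g') comes from a fresh off-target search of g'.
Controls: non-targeting guides are random 20-mers with no genomic window
within Hamming distance 3 on either strand; safe-targeting guides cut in
curated safe-harbor regions and are ranked by specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .fm_index import FMIndex
from .genome_io import Annotation, GenomicInterval
from .guide_database import GuideRecord
from .offtarget_search import (
    PamSpec,
    SearchBudget,
    cut_site_coord,
    hamming_occurrences,
)
from .scoring import (
    CFDTable,
    EfficiencyModel,
    five_prime_g_variant,
    library_score,
    specificity_with_implied_on_target,
)


class LibraryError(ValueError):
    pass


@dataclass
class LibraryConfig:
    min_efficiency: float = 0.25
    min_specificity: float = 0.20
    gc_min: float = 0.20
    gc_max: float = 0.80
    max_monopolymer: int = 3
    guides_per_gene: int = 6
    score_weight: float = 1.25
    n_safe_controls: int = 5000
    n_nontargeting_controls: int = 5000
    control_hamming_radius: int = 3


@dataclass
class FilterReport:
    """Ordered (stage name, survivor count) pairs; counts never increase."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    final_ids: list[str] = field(default_factory=list)

    def add(self, name: str, survivors: list) -> None:
        self.stages.append((name, len(survivors)))

    @property
    def counts(self) -> list[int]:
        return [n for _, n in self.stages]


def gc_fraction(spacer: str) -> float:
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def max_monopolymer_run(spacer: str) -> int:
    best = run = 1
    for a, b in zip(spacer, spacer[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _cds_trees(annotation: Annotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gid, iv in annotation.all_cds():
        trees.setdefault(iv.sequence, IntervalTree()).addi(iv.start, iv.end, gid)
    return trees


def cut_site_genes(record: GuideRecord, trees: dict[str, IntervalTree]) -> list[str]:
    seq, pos = cut_site_coord(record.sequence, record.start, record.end, record.strand)
    if seq not in trees:
        return []
    return sorted({hit.data for hit in trees[seq][pos]})


def apply_library_filters(
    records: list[GuideRecord],
    index: FMIndex,
    annotation: Annotation,
    config: LibraryConfig = LibraryConfig(),
) -> tuple[list[GuideRecord], FilterReport]:
    """Run the six-stage cascade; returns survivors and the stage report."""
    report = FilterReport()
    report.add("input", records)

    for rec in records:
        if rec.specificity is None or rec.efficiency is None:
            raise LibraryError(f"guide {rec.guide_id} is missing scores")

    survivors = [
        r
        for r in records
        if r.offtarget_summary.get(0, 0) + r.offtarget_summary.get(1, 0) == 0
    ]
    report.add("unique_within_1_mismatch", survivors)

    trees = _cds_trees(annotation)
    survivors = [r for r in survivors if cut_site_genes(r, trees)]
    report.add("cuts_in_cds", survivors)

    survivors = [r for r in survivors if r.efficiency >= config.min_efficiency]
    report.add("efficiency", survivors)

    survivors = [r for r in survivors if r.specificity >= config.min_specificity]
    report.add("specificity", survivors)

    survivors = [
        r for r in survivors if config.gc_min <= gc_fraction(r.spacer) <= config.gc_max
    ]
    report.add("gc_content", survivors)

    survivors = [
        r for r in survivors if max_monopolymer_run(r.spacer) <= config.max_monopolymer
    ]
    report.add("monopolymer", survivors)

    report.final_ids = [r.guide_id for r in survivors]
    return survivors, report


@dataclass
class LibraryGuide:
    gene_id: str
    record: GuideRecord
    spacer_5pG: str
    specificity_5pG: float
    score: float
    rank: int


def select_guides_per_gene(
    records: list[GuideRecord],
    annotation: Annotation,
    config: LibraryConfig,
    index: FMIndex,
    cfd_table: CFDTable,
    efficiency_model: EfficiencyModel | None = None,
    pam: PamSpec = PamSpec(),
    budget: SearchBudget = SearchBudget(3, 0, 0),
    genome=None,
) -> tuple[dict[str, list[LibraryGuide]], list[str]]:
    """Per-gene top-k selection by the library score.

    A guide whose cut site lies in CDS of several genes competes for each
    of them. Genes with no surviving guide are returned in the
    no-coverage list rather than raising.
    """
    trees = _cds_trees(annotation)
    by_gene: dict[str, list[GuideRecord]] = {}
    for rec in records:
        for gid in cut_site_genes(rec, trees):
            by_gene.setdefault(gid, []).append(rec)

    spec_gprime_cache: dict[str, float] = {}

    def spec_gprime(rec: GuideRecord) -> float:
        gp = five_prime_g_variant(rec.spacer)
        if gp not in spec_gprime_cache:
            spec_gprime_cache[gp] = specificity_with_implied_on_target(
                index, gp, pam, budget, cfd_table, genome=genome
            ).specificity
        return spec_gprime_cache[gp]

    selected: dict[str, list[LibraryGuide]] = {}
    for gid, recs in by_gene.items():
        scored = []
        for rec in recs:
            eff = (
                rec.efficiency
                if rec.efficiency is not None
                else efficiency_model(rec.spacer)
                if efficiency_model
                else None
            )
            if eff is None or rec.specificity is None:
                raise LibraryError(f"guide {rec.guide_id} is missing scores")
            sp = spec_gprime(rec)
            score = library_score(rec.specificity, sp, eff, config.score_weight)
            scored.append((score, rec, sp))
        # score desc, then specificity desc, then coordinate asc
        scored.sort(key=lambda t: (-t[0], -t[1].specificity, t[1].start, t[1].strand))
        top = scored[: config.guides_per_gene]
        selected[gid] = [
            LibraryGuide(
                gene_id=gid,
                record=rec,
                spacer_5pG=five_prime_g_variant(rec.spacer),
                specificity_5pG=sp,
                score=score,
                rank=i + 1,
            )
            for i, (score, rec, sp) in enumerate(top)
        ]
    no_coverage = sorted(set(annotation.gene_ids) - set(selected))
    return selected, no_coverage


def make_nontargeting_controls(
    index: FMIndex,
    n: int,
    radius: int = 3,
    length: int = 20,
    seed: int = 0,
    max_attempts_per_control: int = 1000,
) -> list[str]:
    """Random spacers with no genomic window within Hamming ``radius`` on
    either strand (PAM-free); reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    controls: list[str] = []
    seen: set[str] = set()
    attempts = 0
    cap = n * max_attempts_per_control
    while len(controls) < n:
        if attempts >= cap:
            raise LibraryError(
                f"could not find {n} non-targeting controls in {attempts} attempts"
            )
        attempts += 1
        spacer = "".join(rng.choice(list("ACGT"), size=length))
        if spacer in seen:
            continue
        seen.add(spacer)
        if hamming_occurrences(index, spacer, radius) == 0:
            controls.append(spacer)
    return controls


def select_safe_targeting(
    records: list[GuideRecord],
    safe_regions: list[GenomicInterval],
    n: int,
    config: LibraryConfig = LibraryConfig(),
) -> list[GuideRecord]:
    """Guides cutting inside safe-harbor regions, passing the applicable
    cascade stages (all but the CDS requirement), top ``n`` by
    specificity with ties broken by coordinate."""
    trees: dict[str, IntervalTree] = {}
    for iv in safe_regions:
        trees.setdefault(iv.sequence, IntervalTree()).addi(iv.start, iv.end, iv.label)

    eligible = []
    for rec in records:
        seq, pos = cut_site_coord(rec.sequence, rec.start, rec.end, rec.strand)
        if seq not in trees or not trees[seq][pos]:
            continue
        if rec.offtarget_summary.get(0, 0) + rec.offtarget_summary.get(1, 0) > 0:
            continue
        if rec.efficiency is not None and rec.efficiency < config.min_efficiency:
            continue
        if rec.specificity is None or rec.specificity < config.min_specificity:
            continue
        if not config.gc_min <= gc_fraction(rec.spacer) <= config.gc_max:
            continue
        if max_monopolymer_run(rec.spacer) > config.max_monopolymer:
            continue
        eligible.append(rec)
    eligible.sort(key=lambda r: (-r.specificity, r.sequence, r.start, r.strand))
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} safe-targeting guides available (requested {n})"
        )
    return eligible[:n]


def rank_problem_genes(
    guides_by_gene: dict[str, list[GuideRecord]],
    mode: str = "specificity",
) -> tuple[list[tuple[str, float]], list[str]]:
    """Rank genes by how off-target-prone their worst guides are.

    ``specificity`` mode sorts ascending by the mean of the two lowest
    guide specificities; ``offtarget_count`` sorts descending by the mean
    of the two largest total off-target counts. Genes with fewer than two
    guides are excluded (returned separately)."""
    if mode not in ("specificity", "offtarget_count"):
        raise LibraryError(f"unknown mode {mode!r}")
    ranked: list[tuple[str, float]] = []
    excluded: list[str] = []
    for gid, recs in guides_by_gene.items():
        if len(recs) < 2:
            excluded.append(gid)
            continue
        if mode == "specificity":
            worst = sorted(r.specificity for r in recs)[:2]
            ranked.append((gid, sum(worst) / 2))
        else:
            counts = sorted(
                (sum(r.offtarget_summary.values()) for r in recs), reverse=True
            )[:2]
            ranked.append((gid, sum(counts) / 2))
    reverse = mode == "offtarget_count"
    ranked.sort(key=lambda t: (-t[1] if reverse else t[1], t[0]))
    return ranked, sorted(excluded)
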