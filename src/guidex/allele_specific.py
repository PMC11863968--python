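"""Allele-specific guide design for hybrid diploid genomes.

Workflow: apply strain variants (SNPs and small indels) to the reference
to build a pseudo-genome representing the second allele, construct a guide
database against each genome, then cross-exclude: a guide from genome A is
A-specific only if its spacer has zero perfect PAM-adjacent occurrences
(primary or an alternative PAM — an NAG-adjacent perfect protospacer in
the other allele can still cut) in genome B, and symmetrically. Survivors
are annotated with off-targets in both genomes, classified by what makes
them discriminating (a variant in the PAM, in the protospacer, or a larger
structural difference), and optionally reduced to a high-confidence subset
by a second filter cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .fm_index import FMIndex
from .genome_io import Annotation, Genome, GenomicInterval
from .guide_database import GuideRecord
from .library_design import FilterReport
from .offtarget_search import (
    GuideQuery,
    PamSpec,
    SearchBudget,
    cut_site_coord,
    enumerate_offtargets,
    find_perfect_sites,
)


class AlleleError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """A SNP or small indel in reference coordinates (0-based).

    ``ref``/``alt`` follow VCF conventions after trimming: a SNP has
    len(ref) == len(alt) == 1; an insertion/deletion carries the shared
    anchor base first.
    """

    sequence: str
    position: int
    ref: str
    alt: str
    zygosity: str | None = None  # {hom, het} when genotypes are available

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def end(self) -> int:
        return self.position + len(self.ref)


@dataclass
class CoordinateMap:
    """Piecewise-linear reference -> pseudo-genome coordinate map.

    ``breaks``/``shifts`` per sequence: for reference position p, the
    mapped position is p + shift of the last break <= p; positions inside
    a deleted interval are unmappable.
    """

    breaks: dict[str, np.ndarray]
    shifts: dict[str, np.ndarray]
    deleted: dict[str, list[tuple[int, int]]]

    def map_position(self, sequence: str, pos: int) -> int | None:
        for dstart, dend in self.deleted.get(sequence, []):
            if dstart <= pos < dend:
                return None
        br = self.breaks[sequence]
        idx = int(np.searchsorted(br, pos, side="right")) - 1
        return pos + int(self.shifts[sequence][idx])


def apply_variants(
    genome: Genome, variants: list[Variant]
) -> tuple[Genome, CoordinateMap]:
    """Left-to-right application of sorted, non-overlapping variants.

    Each variant's ref allele is checked against the genome; a mismatch or
    an overlap is a hard error.
    """
    by_seq: dict[str, list[Variant]] = {}
    for v in variants:
        by_seq.setdefault(v.sequence, []).append(v)
    new_seqs: dict[str, str] = {}
    breaks: dict[str, np.ndarray] = {}
    shifts: dict[str, np.ndarray] = {}
    deleted: dict[str, list[tuple[int, int]]] = {}
    for name, seq in genome.sequences.items():
        vs = sorted(by_seq.get(name, []), key=lambda v: v.position)
        pieces: list[str] = []
        brk = [0]
        shf = [0]
        dels: list[tuple[int, int]] = []
        cursor = 0
        shift = 0
        for v in vs:
            if v.position < cursor:
                raise AlleleError(
                    f"overlapping variants at {name}:{v.position} (previous ends {cursor})"
                )
            observed = seq[v.position : v.end]
            if observed != v.ref:
                raise AlleleError(
                    f"ref mismatch at {name}:{v.position}: genome has "
                    f"{observed!r}, variant says {v.ref!r}"
                )
            pieces.append(seq[cursor : v.position])
            pieces.append(v.alt)
            delta = len(v.alt) - len(v.ref)
            if delta < 0:
                # bases after the retained alt prefix are deleted
                dels.append((v.position + len(v.alt), v.end))
            cursor = v.end
            shift += delta
            brk.append(cursor)
            shf.append(shift)
        pieces.append(seq[cursor:])
        new_seqs[name] = "".join(pieces)
        breaks[name] = np.asarray(brk, dtype=np.int64)
        shifts[name] = np.asarray(shf, dtype=np.int64)
        deleted[name] = dels
    return Genome(new_seqs), CoordinateMap(breaks, shifts, deleted)


def read_vcf(path: str) -> list[Variant]:
    """Read SNPs/indels from a VCF; only position, ref, alt and genotype
    are consumed. Multi-allelic records take the first alt."""
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            alt = rec.alts[0]
            if set(alt) - set("ACGT") or set(rec.ref) - set("ACGT"):
                continue  # symbolic or ambiguous alleles are skipped
            zygosity = None
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and None not in gt:
                    zygosity = "hom" if len(set(gt)) == 1 else "het"
            out.append(
                Variant(
                    sequence=rec.chrom,
                    position=rec.pos - 1,
                    ref=rec.ref,
                    alt=alt,
                    zygosity=zygosity,
                )
            )
    return out


def write_vcf(variants: list[Variant], genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.sequence, v.position)):
            gt = "0/1" if v.zygosity == "het" else "1/1"
            fh.write(
                f"{v.sequence}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


@dataclass
class AlleleSpecificRecord:
    """A guide unique to one allele of the hybrid, with two-genome
    off-target summaries."""

    record: GuideRecord
    target_allele: str  # "A" or "B"
    discrimination: str = "structural"
    offtargets_in_A: dict[int, int] = field(default_factory=dict)
    offtargets_in_B: dict[int, int] = field(default_factory=dict)
    overlapping_variants: list[Variant] = field(default_factory=list)
    gene: str | None = None

    @property
    def guide_id(self) -> str:
        return f"{self.target_allele}|{self.record.guide_id}"


def _summary(offs, k: int) -> dict[int, int]:
    out = {d: 0 for d in range(k + 1)}
    for o in offs:
        if not (o.rna_bulges or o.dna_bulges):
            out[o.distance] += 1
    return out


def design_allele_specific(
    db_a: list[GuideRecord],
    index_b: FMIndex,
    db_b: list[GuideRecord],
    index_a: FMIndex,
    pam: PamSpec = PamSpec(),
    budget: SearchBudget = SearchBudget(3, 0, 0),
    check_alternative_pams: bool = True,
) -> tuple[list[AlleleSpecificRecord], list[AlleleSpecificRecord]]:
    """Cross-genome exclusion: guides of genome A with zero perfect
    occurrences in genome B form the A-specific set, and symmetrically.
    Survivors are annotated with off-target summaries in both genomes.

    ``check_alternative_pams`` extends the perfect-match exclusion to
    alternative PAMs (the conservative default)."""

    def one_side(db_own, index_own, index_other, label):
        out: list[AlleleSpecificRecord] = []
        for rec in db_own:
            perfect_other = find_perfect_sites(
                index_other,
                rec.spacer,
                pam,
                primary_only=not check_alternative_pams,
            )
            if perfect_other:
                continue
            query = GuideQuery(rec.spacer, pam)
            offs_other = enumerate_offtargets(
                index_other, query, budget, include_on_target=True
            )
            own_summary = dict(rec.offtarget_summary)
            other_summary = _summary(offs_other, budget.max_mismatches)
            own_key = "A" if label == "A" else "B"
            other_key = "B" if label == "A" else "A"
            out.append(
                AlleleSpecificRecord(
                    record=rec,
                    target_allele=label,
                    **{
                        f"offtargets_in_{own_key}": own_summary,
                        f"offtargets_in_{other_key}": other_summary,
                    },
                )
            )
        return out

    return one_side(db_a, index_a, index_b, "A"), one_side(db_b, index_b, index_a, "B")


def classify_discrimination(
    record: GuideRecord,
    variants: list[Variant],
    pam_length: int = 3,
) -> tuple[str, list[Variant]]:
    """Why is this guide allele-discriminating?

    ``pam_variant`` if any variant overlaps the PAM window, else
    ``protospacer_variant`` if any overlaps the protospacer, else
    ``structural``. Variant positions must be expressed in the coordinate
    system of the genome the record was designed against (project through
    the coordinate map for pseudo-genome records)."""
    if record.strand == "+":
        pam_iv = (record.end, record.end + pam_length)
    else:
        pam_iv = (record.start - pam_length, record.start)
    proto_iv = (record.start, record.end)

    def overlaps(v: Variant, iv: tuple[int, int]) -> bool:
        span = max(len(v.ref), len(v.alt))
        return v.sequence == record.sequence and v.position < iv[1] and v.position + span > iv[0]

    pam_hits = [v for v in variants if overlaps(v, pam_iv)]
    if pam_hits:
        return "pam_variant", pam_hits
    proto_hits = [v for v in variants if overlaps(v, proto_iv)]
    if proto_hits:
        return "protospacer_variant", proto_hits
    return "structural", []


def project_variants(variants: list[Variant], cmap: CoordinateMap) -> list[Variant]:
    """Express variants in pseudo-genome coordinates (alt allele spans)."""
    out = []
    for v in variants:
        mapped = cmap.map_position(v.sequence, v.position)
        if mapped is None:
            continue
        out.append(Variant(v.sequence, mapped, v.alt, v.alt, v.zygosity))
    return out


@dataclass
class HighConfidenceConfig:
    exclude_het: bool = True
    max_2mm: int = 0
    max_3mm: int = 3
    efficiency_quantile: float = 0.75
    repeat_distance: int = 200
    repeats: list[GenomicInterval] = field(default_factory=list)


def high_confidence_filter(
    records: list[AlleleSpecificRecord],
    config: HighConfidenceConfig = HighConfidenceConfig(),
) -> tuple[list[AlleleSpecificRecord], FilterReport]:
    """Stages, in order: drop guides annotated with heterozygous variants
    (when zygosity is known); no 2-mismatch off-targets in either genome;
    at most ``max_3mm`` 3-mismatch off-targets in either genome; cutting
    efficiency in the top quantile of the surviving set; cut site at least
    ``repeat_distance`` bp from any annotated repeat."""
    report = FilterReport()
    report.add("input", records)

    survivors = records
    if config.exclude_het:
        survivors = [
            r
            for r in survivors
            if not any(v.zygosity == "het" for v in r.overlapping_variants)
        ]
    report.add("homozygous_variants_only", survivors)

    survivors = [
        r
        for r in survivors
        if r.offtargets_in_A.get(2, 0) <= config.max_2mm
        and r.offtargets_in_B.get(2, 0) <= config.max_2mm
    ]
    report.add("no_2mm_offtargets", survivors)

    survivors = [
        r
        for r in survivors
        if r.offtargets_in_A.get(3, 0) <= config.max_3mm
        and r.offtargets_in_B.get(3, 0) <= config.max_3mm
    ]
    report.add("max_3mm_offtargets", survivors)

    effs = [r.record.efficiency for r in survivors]
    if any(e is None for e in effs):
        missing = [r.guide_id for r in survivors if r.record.efficiency is None][:3]
        raise AlleleError(f"efficiency required for quantile stage; missing for {missing}")
    if survivors:
        threshold = float(np.quantile(np.asarray(effs), config.efficiency_quantile))
        survivors = [r for r in survivors if r.record.efficiency >= threshold]
    report.add("top_efficiency", survivors)

    if config.repeats:
        trees: dict[str, IntervalTree] = {}
        for iv in config.repeats:
            trees.setdefault(iv.sequence, IntervalTree()).addi(iv.start, iv.end)

        def far_from_repeats(r: AlleleSpecificRecord) -> bool:
            seq, pos = cut_site_coord(
                r.record.sequence, r.record.start, r.record.end, r.record.strand
            )
            if seq not in trees:
                return True
            lo = pos - config.repeat_distance
            hi = pos + config.repeat_distance + 1
            return not trees[seq].overlap(lo, hi)

        survivors = [r for r in survivors if far_from_repeats(r)]
    report.add("repeat_distance", survivors)
    report.final_ids = [r.guide_id for r in survivors]
    return survivors, report


def annotate_genes(
    records: list[AlleleSpecificRecord], annotation: Annotation
) -> list[AlleleSpecificRecord]:
    """Tag each record with the gene whose exon contains its cut site;
    among multiple qualifying genes, the lexicographically smallest id is
    chosen (a deterministic stand-in for an arbitrary choice)."""
    trees: dict[str, IntervalTree] = {}
    for gid, iv in annotation.all_exons():
        trees.setdefault(iv.sequence, IntervalTree()).addi(iv.start, iv.end, gid)
    for rec in records:
        seq, pos = cut_site_coord(
            rec.record.sequence, rec.record.start, rec.record.end, rec.record.strand
        )
        hits = sorted(h.data for h in trees.get(seq, IntervalTree())[pos])
        rec.gene = hits[0] if hits else None
    return records
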