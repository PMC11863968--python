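"""Reproducible synthetic genomes, annotations, variants and planted
off-target scenarios.

Everything every other module needs for testing is generated here from a
seed — no downloads. Planted-site truth tables are re-verified with the
brute-force scanners so that accidental background matches in the random
filler are folded into the truth set instead of breaking oracles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .allele_specific import Variant, apply_variants
from .bruteforce import scan_offtargets, scan_offtargets_bulged
from .genome_io import Annotation, Genome, GenomicInterval, reverse_complement
from .offtarget_search import OffTarget, PamSpec, SearchBudget, expand_pam

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class FixtureError(ValueError):
    pass


def random_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    n_sequences: int = 1,
    name_prefix: str = "chr",
) -> Genome:
    """I.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if length <= 0:
        raise FixtureError("length must be positive")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    per = length // n_sequences
    seqs = {}
    for i in range(n_sequences):
        n = per if i < n_sequences - 1 else length - per * (n_sequences - 1)
        seqs[f"{name_prefix}{i + 1}"] = "".join(rng.choice(bases, size=n, p=p))
    return Genome(seqs)


@dataclass(frozen=True)
class PlantedSite:
    """One requested off-target planting.

    ``position`` is where the full site string (protospacer + PAM on the
    plus strand; its reverse complement for minus placements) is written.
    ``mismatches`` random spacer positions are mutated (transitions, so
    CFD values are predictable); ``rna_bulge_at`` deletes that spacer
    position from the genomic copy; ``dna_bulge`` inserts a base after the
    given spacer gap.
    """

    position: int
    strand: str = "+"
    sequence: str | None = None
    mismatches: int = 0
    mismatch_positions: tuple[int, ...] = ()
    rna_bulge_at: int | None = None
    dna_bulge: tuple[int, str] | None = None
    pam: str | None = None


def _site_string(spacer: str, site: PlantedSite, pam_spec: PamSpec, rng) -> str:
    L = len(spacer)
    positions = list(site.mismatch_positions)
    blocked = {site.rna_bulge_at} if site.rna_bulge_at else set()
    if site.dna_bulge:
        blocked |= {site.dna_bulge[0], site.dna_bulge[0] + 1}
    while len(positions) < site.mismatches:
        p = int(rng.integers(1, L + 1))
        if p not in positions and p not in blocked:
            positions.append(p)
    chars = list(spacer)
    for p in positions:
        chars[p - 1] = _TRANSITION[chars[p - 1]]
    if site.rna_bulge_at is not None:
        if not 2 <= site.rna_bulge_at <= L - 1:
            raise FixtureError("RNA bulge must be interior to the spacer")
        chars[site.rna_bulge_at - 1] = ""
    if site.dna_bulge is not None:
        gap, base = site.dna_bulge
        if not 1 <= gap <= L - 1:
            raise FixtureError("DNA bulge gap must be interior to the spacer")
        chars[gap - 1] = chars[gap - 1] + base
    pam = site.pam or expand_pam(pam_spec.primary)[0]
    window = "".join(chars)
    full = window + pam
    return full if site.strand == "+" else reverse_complement(full)


def plant_sites(
    genome: Genome,
    spacer: str,
    pam: PamSpec,
    placements: list[PlantedSite],
    budget: SearchBudget = SearchBudget(3, 0, 0),
    seed: int = 0,
) -> tuple[Genome, list[OffTarget]]:
    """Write mutated spacer+PAM copies into the genome and return the
    mutated genome plus the exact truth table of sites within ``budget``.

    The truth table comes from re-scanning the mutated genome with the
    brute-force oracle, so accidental background matches are included;
    every requested planting is asserted to be present.
    """
    seqs = dict(genome.sequences)
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for site in placements:
        seq_name = site.sequence or genome.names[0]
        text = _site_string(spacer, site, pam, rng)
        start, end = site.position, site.position + len(text)
        if end > len(seqs[seq_name]):
            raise FixtureError(f"placement at {seq_name}:{start} exceeds the sequence")
        for a, b in occupied.get(seq_name, []):
            if start < b and end > a:
                raise FixtureError(f"overlapping placements at {seq_name}:{start}")
        occupied.setdefault(seq_name, []).append((start, end))
        s = seqs[seq_name]
        seqs[seq_name] = s[:start] + text + s[end:]
    mutated = Genome(seqs)

    if budget.max_rna_bulges or budget.max_dna_bulges:
        truth = scan_offtargets_bulged(mutated, spacer, pam, budget)
    else:
        truth = scan_offtargets(mutated, spacer, pam, budget.max_mismatches)

    loci = {(t.sequence, t.strand, t.pam_start) for t in truth}
    for site in placements:
        seq_name = site.sequence or genome.names[0]
        wlen = (
            len(spacer)
            - (1 if site.rna_bulge_at is not None else 0)
            + (1 if site.dna_bulge is not None else 0)
        )
        if site.strand == "+":
            pam_start = site.position + wlen
        else:
            pam_start = site.position
        if (seq_name, site.strand, pam_start) not in loci:
            raise FixtureError(
                f"planted site at {seq_name}:{site.position}{site.strand} was not "
                "recovered by the verification scan (budget too small?)"
            )
    return mutated, truth


def toy_annotation(
    genome: Genome,
    n_genes: int = 5,
    exons_per_gene: int = 2,
    seed: int = 0,
) -> Annotation:
    """Evenly spaced, non-overlapping genes with nested exon/CDS features
    on the first sequence; deterministic."""
    name = genome.names[0]
    length = genome.lengths[name]
    span = length // n_genes
    if span < 40 * exons_per_gene:
        raise FixtureError("genome too small for the requested annotation")
    genes, exons, cds = {}, {}, {}
    for i in range(n_genes):
        gid = f"gene{i + 1}"
        gstart = i * span + span // 10
        gend = (i + 1) * span - span // 10
        strand = "+" if i % 2 == 0 else "-"
        genes[gid] = GenomicInterval(name, gstart, gend, strand, gid)
        exon_span = (gend - gstart) // exons_per_gene
        exons[gid] = []
        cds[gid] = []
        for j in range(exons_per_gene):
            estart = gstart + j * exon_span
            eend = estart + max(30, exon_span // 2)
            exons[gid].append(GenomicInterval(name, estart, eend, strand, gid))
            cds[gid].append(GenomicInterval(name, estart, eend, strand, gid))
    return Annotation(genes=genes, exons=exons, cds=cds)


def simulate_diploid(
    genome: Genome,
    snp_rate: float = 0.002,
    indel_rate: float = 0.0002,
    seed: int = 0,
    het_fraction: float = 0.0,
    forced_variants: list[Variant] | None = None,
) -> tuple[list[Variant], Genome]:
    """Random strain variants (SNPs and 1-3 bp indels) plus the
    pseudo-genome they imply. Overlapping draws are rejected; forced
    variants take precedence over random ones."""
    rng = np.random.default_rng(seed)
    variants: list[Variant] = list(forced_variants or [])
    taken: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        taken.setdefault(v.sequence, []).append((v.position - 1, v.end + 1))

    def free(seq: str, a: int, b: int) -> bool:
        return all(b <= x or a >= y for x, y in taken.get(seq, []))

    for name, seq in genome.sequences.items():
        n = len(seq)
        snp_pos = np.nonzero(rng.random(n) < snp_rate)[0]
        for p in snp_pos:
            p = int(p)
            ref = seq[p]
            if ref == "N" or not free(name, p - 1, p + 2):
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            zyg = "het" if rng.random() < het_fraction else "hom"
            variants.append(Variant(name, p, ref, str(alt), zyg))
            taken.setdefault(name, []).append((p - 1, p + 2))
        indel_pos = np.nonzero(rng.random(n) < indel_rate)[0]
        for p in indel_pos:
            p = int(p)
            size = int(rng.integers(1, 4))
            if p + size + 1 >= n:
                continue
            ref_anchor = seq[p]
            if ref_anchor == "N" or not free(name, p - 1, p + size + 2):
                continue
            zyg = "het" if rng.random() < het_fraction else "hom"
            if rng.random() < 0.5:
                ins = "".join(rng.choice(list("ACGT"), size=size))
                variants.append(Variant(name, p, ref_anchor, ref_anchor + ins, zyg))
            else:
                ref = seq[p : p + size + 1]
                if "N" in ref:
                    continue
                variants.append(Variant(name, p, ref, ref_anchor, zyg))
            taken.setdefault(name, []).append((p - 1, p + size + 2))
    variants.sort(key=lambda v: (v.sequence, v.position))
    pseudo, _ = apply_variants(genome, variants)
    return variants, pseudo


# -- engineered library-cascade fixture -----------------------------------


@dataclass
class CascadeFixture:
    """Twelve engineered guides, one removed by each cascade stage."""

    genome: Genome
    annotation: Annotation
    candidates: list  # guide_database.Candidate, in order G1..G12
    efficiencies: dict[str, float]
    spacers: dict[str, str] = field(default_factory=dict)
    removed_by_stage: dict[str, str] = field(default_factory=dict)


def library_cascade_fixture(seed: int = 20) -> CascadeFixture:
    """Deterministic genome + annotation + 12 candidate guides engineered
    so that each cascade stage removes exactly one guide:

    G7   extra 1-mismatch occurrence      -> uniqueness stage
    G8   cut site outside any CDS         -> CDS stage
    G9   efficiency 0.10                  -> efficiency stage
    G10  six planted 2-mismatch sites     -> specificity stage
    G11  85% G+C                          -> GC stage
    G12  AAAA monopolymer                 -> monopolymer stage
    """
    from .guide_database import Candidate

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand_spacer() -> str:
        # rejection-sample so only the engineered guides violate a stage
        while True:
            s = "".join(rng.choice(bases, size=20))
            gc = (s.count("G") + s.count("C")) / 20
            run = max(len(r) for r in re.findall(r"A+|C+|G+|T+", s))
            if 0.3 <= gc <= 0.7 and run <= 3:
                return s

    spacers = {f"G{i}": rand_spacer() for i in range(1, 11)}
    # G11: 17/20 G+C, no run > 3
    spacers["G11"] = "GCGCCGGCGCGGCCGCGTAC"[:20]
    # G12: interior AAAA run, balanced GC
    g12 = list(rand_spacer())
    g12[5:9] = list("AAAA")
    g12[9] = "C"  # guard against a 5-run
    g12[4] = "C"
    spacers["G12"] = "".join(g12)

    genome = random_genome(6000, gc=0.5, seed=seed + 1)
    name = genome.names[0]
    seq = list(genome.sequences[name])

    def write(pos: int, text: str) -> None:
        seq[pos : pos + len(text)] = list(text)

    candidates: list[Candidate] = []
    pos = 200
    in_gene = [f"G{i}" for i in range(1, 8)] + ["G9", "G10", "G11", "G12"]
    for gname in in_gene:
        write(pos, spacers[gname] + "AGG")
        candidates.append(
            Candidate(name, pos, pos + 20, "+", spacers[gname], "AGG")
        )
        pos += 100
    gene_end = pos + 10
    g8_pos = pos + 200
    write(g8_pos, spacers["G8"] + "AGG")
    candidates.insert(7, Candidate(name, g8_pos, g8_pos + 20, "+", spacers["G8"], "AGG"))

    copy_pos = g8_pos + 300
    # G7: one extra 1-mismatch AGG occurrence (transition at position 10)
    g7_copy = list(spacers["G7"])
    g7_copy[9] = _TRANSITION[g7_copy[9]]
    write(copy_pos, "".join(g7_copy) + "AGG")
    copy_pos += 100
    # G10: six 2-mismatch AGG occurrences (transitions at positions 1 and 2)
    g10_copy = list(spacers["G10"])
    g10_copy[0] = _TRANSITION[g10_copy[0]]
    g10_copy[1] = _TRANSITION[g10_copy[1]]
    for _ in range(6):
        write(copy_pos, "".join(g10_copy) + "AGG")
        copy_pos += 100

    genome = Genome({name: "".join(seq)})
    gene = GenomicInterval(name, 150, gene_end, "+", "gene1")
    annotation = Annotation(
        genes={"gene1": gene},
        exons={"gene1": [gene]},
        cds={"gene1": [gene]},
    )
    efficiencies = {spacers[g]: 0.60 for g in spacers}
    efficiencies[spacers["G9"]] = 0.10
    order = [f"G{i}" for i in range(1, 13)]
    candidates_by_name = {c.spacer: c for c in candidates}
    ordered = [candidates_by_name[spacers[g]] for g in order]
    return CascadeFixture(
        genome=genome,
        annotation=annotation,
        candidates=ordered,
        efficiencies=efficiencies,
        spacers=spacers,
        removed_by_stage={
            "unique_within_1_mismatch": "G7",
            "cuts_in_cds": "G8",
            "efficiency": "G9",
            "specificity": "G10",
            "gc_content": "G11",
            "monopolymer": "G12",
        },
    )
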