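"""Genome-wide gRNA database construction and SAM emission.

Pipeline: enumerate every primary-PAM candidate window on both strands,
drop candidates whose spacer has more than one perfect primary-PAM
occurrence genome-wide, annotate survivors with all off-targets within the
search budget (alternative PAMs included), attach specificity and — when a
model is supplied — cutting efficiency, and emit one SAM alignment line
per guide. Specificity and efficiency live in the ``cs`` and ``ds`` tags;
the off-target list is hex-encoded in the ``of`` tag.

Hex off-target layout (versioned, little-endian): one header byte
(format version, currently 0x01), then per off-target 9 bytes — a uint64
of ``global_coordinate << 1 | strand_bit`` (strand_bit 1 for minus;
global coordinate is the protospacer start in the concatenated-genome
coordinate system embedded in the index) followed by a uint8 mismatch
distance. Rendered as lowercase hex for the SAM ``H`` tag.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .fm_index import FMIndex
from .genome_io import Genome, reverse_complement
from .offtarget_search import (
    GuideQuery,
    OffTarget,
    PamSpec,
    SearchBudget,
    enumerate_offtargets,
    find_perfect_sites,
)
from .scoring import (
    SPACER_LENGTH,
    CFDTable,
    EfficiencyModel,
    specificity,
)

_HEX_VERSION = 1


class DatabaseError(ValueError):
    pass


@dataclass(frozen=True)
class Candidate:
    """A primary-PAM protospacer window found in the genome."""

    sequence: str
    start: int
    end: int
    strand: str
    spacer: str
    pam: str


@dataclass
class DatabaseParams:
    spacer_length: int = 20
    pam: PamSpec = field(default_factory=PamSpec)
    budget: SearchBudget = field(default_factory=lambda: SearchBudget(3, 0, 0))
    partitions: int = 1

    def __post_init__(self):
        if self.partitions < 1:
            raise DatabaseError("partitions must be >= 1")


@dataclass
class GuideRecord:
    """One database row: a uniquely targeting guide and its off-targets."""

    guide_id: str
    sequence: str
    start: int
    end: int
    strand: str
    spacer: str
    pam: str
    specificity: float | None = None
    efficiency: float | None = None
    offtarget_summary: dict[int, int] = field(default_factory=dict)
    offtargets: list[OffTarget] = field(default_factory=list)

    def sort_key(self, seq_order: dict[str, int]) -> tuple:
        return (seq_order[self.sequence], self.start, self.strand)


def enumerate_candidates(
    genome: Genome, pam: PamSpec = PamSpec(), length: int = 20
) -> list[Candidate]:
    """Every window of ``length`` followed by a primary-PAM match, both
    strands, excluding windows or PAMs containing N; sorted by (sequence,
    position, strand) with + before -."""
    from .bruteforce import _encode, _pam_match_vector

    plen = pam.length
    out: list[Candidate] = []
    for seq_name, ref in genome.sequences.items():
        n = len(ref)
        if n < length + plen:
            continue
        for strand in "+-":
            text = ref if strand == "+" else reverse_complement(ref)
            codes = _encode(text)
            starts = np.arange(n - length - plen + 1)
            win = np.lib.stride_tricks.sliding_window_view(codes, length)[starts]
            pam_win = np.lib.stride_tricks.sliding_window_view(codes, plen)[
                starts + length
            ]
            ok = _pam_match_vector(codes, starts + length, pam.primary)
            ok &= ~(win == 4).any(axis=1)
            ok &= ~(pam_win == 4).any(axis=1)
            for p in np.nonzero(ok)[0]:
                p = int(p)
                if strand == "+":
                    start, end = p, p + length
                else:
                    start, end = n - p - length, n - p
                out.append(
                    Candidate(
                        sequence=seq_name,
                        start=start,
                        end=end,
                        strand=strand,
                        spacer=text[p : p + length],
                        pam=text[p + length : p + length + plen],
                    )
                )
    order = {name: i for i, name in enumerate(genome.sequences)}
    out.sort(key=lambda c: (order[c.sequence], c.start, 0 if c.strand == "+" else 1))
    return out


def _check_index_genome(index: FMIndex, genome: Genome) -> None:
    if index.seq_names != genome.names or index.seq_lengths != [
        genome.lengths[s] for s in genome.names
    ]:
        raise DatabaseError("index was not built from this genome")


def build_database(
    index: FMIndex,
    candidates: list[Candidate],
    params: DatabaseParams,
    cfd_table: CFDTable | None = None,
    efficiency_model: EfficiencyModel | None = None,
    genome: Genome | None = None,
) -> list[GuideRecord]:
    """Annotate uniquely targeting candidates with off-targets and scores.

    Candidates whose spacer occurs perfectly (primary PAM) more than once
    genome-wide are dropped; each surviving record's own locus is excluded
    from its off-target list.
    """
    if genome is not None:
        _check_index_genome(index, genome)
    records: list[GuideRecord] = []
    for cand in candidates:
        perfect = find_perfect_sites(
            index, cand.spacer, params.pam, primary_only=True, genome=genome
        )
        if len(perfect) != 1:
            continue
        query = GuideQuery(
            cand.spacer,
            params.pam,
            declared_on_target=(cand.sequence, cand.start, cand.strand),
        )
        offs = enumerate_offtargets(index, query, params.budget, genome=genome)
        summary = {d: 0 for d in range(params.budget.max_mismatches + 1)}
        for off in offs:
            if not (off.rna_bulges or off.dna_bulges):
                summary[off.distance] += 1
        spec_val = None
        if cfd_table is not None and len(cand.spacer) == SPACER_LENGTH:
            spec_val = specificity(query, offs, cfd_table).specificity
        eff_val = efficiency_model(cand.spacer) if efficiency_model else None
        records.append(
            GuideRecord(
                guide_id=f"{cand.sequence}:{cand.start}:{cand.strand}",
                sequence=cand.sequence,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                spacer=cand.spacer,
                pam=cand.pam,
                specificity=spec_val,
                efficiency=eff_val,
                offtarget_summary=summary,
                offtargets=offs,
            )
        )
    seq_order = {name: i for i, name in enumerate(index.seq_names)}
    records.sort(key=lambda r: r.sort_key(seq_order))
    return records


# -- hex off-target encoding ---------------------------------------------


def _global_offsets(index_or_genome) -> dict[str, int]:
    if isinstance(index_or_genome, Genome):
        return dict(index_or_genome.offsets)
    return dict(zip(index_or_genome.seq_names, index_or_genome.seq_offsets))


def encode_offtargets_hex(
    offtargets: list[OffTarget] | list[tuple[int, str, int]],
    offsets: dict[str, int] | FMIndex | Genome,
) -> str:
    """Encode (absolute position, strand, distance) triples as hex.

    An empty off-target list encodes as the empty string."""
    if not offtargets:
        return ""
    if not isinstance(offsets, dict):
        offsets = _global_offsets(offsets)
    payload = bytearray([_HEX_VERSION])
    for off in offtargets:
        if isinstance(off, OffTarget):
            gpos = offsets[off.sequence] + off.start
            strand_bit = 1 if off.strand == "-" else 0
            dist = off.distance
        else:
            gpos, strand, dist = off
            strand_bit = 1 if strand == "-" else 0
        word = (int(gpos) << 1) | strand_bit
        payload += word.to_bytes(8, "little")
        if not 0 <= dist <= 255:
            raise DatabaseError(f"distance {dist} does not fit in one byte")
        payload.append(dist)
    return payload.hex()


def decode_offtargets_hex(hexstr: str) -> list[tuple[int, str, int]]:
    """Inverse of :func:`encode_offtargets_hex`: (global position, strand,
    distance) triples."""
    if hexstr == "":
        return []
    try:
        payload = bytes.fromhex(hexstr)
    except ValueError as exc:
        raise DatabaseError("malformed hex payload") from exc
    if payload[0] != _HEX_VERSION:
        raise DatabaseError(f"unsupported hex payload version {payload[0]}")
    body = payload[1:]
    if len(body) % 9 != 0:
        raise DatabaseError("hex payload length is not a whole number of records")
    out = []
    for i in range(0, len(body), 9):
        word = int.from_bytes(body[i : i + 8], "little")
        dist = body[i + 8]
        out.append((word >> 1, "-" if word & 1 else "+", dist))
    return out


# -- SAM ------------------------------------------------------------------


def write_sam(records: list[GuideRecord], genome: Genome, path: str) -> None:
    """Emit one SAM alignment line per guide (1-based POS, FLAG 16 for
    minus-strand guides, SEQ in reference-forward orientation)."""
    offsets = dict(genome.offsets)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in genome.names:
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.lengths[name]}\n")
        fh.write("@PG\tID:guidex\tPN:guidex\n")
        for rec in records:
            if rec.sequence not in offsets:
                raise DatabaseError(f"unknown sequence {rec.sequence!r}")
            flag = 16 if rec.strand == "-" else 0
            seq_fwd = (
                rec.spacer if rec.strand == "+" else reverse_complement(rec.spacer)
            )
            tags = [f"pm:Z:{rec.pam}"]
            if rec.specificity is not None:
                tags.append(f"cs:f:{rec.specificity:.6g}")
            if rec.efficiency is not None:
                tags.append(f"ds:f:{rec.efficiency:.6g}")
            hexstr = encode_offtargets_hex(rec.offtargets, offsets)
            if hexstr:
                tags.append(f"of:H:{hexstr}")
            fh.write(
                "\t".join(
                    [
                        rec.guide_id,
                        str(flag),
                        rec.sequence,
                        str(rec.start + 1),
                        "100",
                        f"{rec.end - rec.start}M",
                        "*",
                        "0",
                        "0",
                        seq_fwd,
                        "*",
                    ]
                    + tags
                )
                + "\n"
            )


def read_sam(path: str, budget_k: int = 3) -> list[GuideRecord]:
    """Read a guide database SAM back into records (inverse of write_sam)."""
    import pysam

    records: list[GuideRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        name_by_tid = list(sam.references)
        offsets: dict[str, int] = {}
        pos = 0
        for name, length in zip(sam.references, sam.lengths):
            offsets[name] = pos
            pos += length + 1
        gpos_to_local = sorted((off, name) for name, off in offsets.items())
        for aln in sam.fetch(until_eof=True):
            strand = "-" if aln.flag & 16 else "+"
            seq_fwd = aln.query_sequence
            spacer = seq_fwd if strand == "+" else reverse_complement(seq_fwd)
            hexstr = aln.get_tag("of") if aln.has_tag("of") else ""
            triples = decode_offtargets_hex(hexstr)
            summary = {d: 0 for d in range(budget_k + 1)}
            offtargets: list[OffTarget] = []
            for gpos, ostrand, dist in triples:
                idx = 0
                for j, (off, _) in enumerate(gpos_to_local):
                    if gpos >= off:
                        idx = j
                seq_name = gpos_to_local[idx][1]
                local = gpos - gpos_to_local[idx][0]
                summary[dist] = summary.get(dist, 0) + 1
                offtargets.append(
                    OffTarget(
                        sequence=seq_name,
                        start=local,
                        end=local + len(spacer),
                        strand=ostrand,
                        matched_protospacer="",
                        matched_pam="NNN",
                        mismatches=[(0, "N", "N")] * dist,
                        pam_class="unknown",
                    )
                )
            records.append(
                GuideRecord(
                    guide_id=aln.query_name,
                    sequence=name_by_tid[aln.reference_id],
                    start=aln.reference_start,
                    end=aln.reference_start + (aln.query_length or len(seq_fwd)),
                    strand=strand,
                    spacer=spacer,
                    pam=aln.get_tag("pm") if aln.has_tag("pm") else "",
                    specificity=float(aln.get_tag("cs")) if aln.has_tag("cs") else None,
                    efficiency=float(aln.get_tag("ds")) if aln.has_tag("ds") else None,
                    offtarget_summary=summary,
                    offtargets=offtargets,
                )
            )
    return records


# -- partitioned runs -----------------------------------------------------


def partition_candidates(
    candidates: list[Candidate], partitions: int
) -> list[list[Candidate]]:
    """Deterministic round-robin split of the (sorted) candidate list."""
    if partitions < 1:
        raise DatabaseError("partitions must be >= 1")
    parts: list[list[Candidate]] = [[] for _ in range(partitions)]
    for i, cand in enumerate(candidates):
        parts[i % partitions].append(cand)
    return parts


def partition_run(
    candidates: list[Candidate],
    partitions: int,
    worker,
    seq_order: dict[str, int],
    threads: int = 1,
) -> list[GuideRecord]:
    """Run ``worker`` (partition -> records) over a round-robin split and
    merge into one globally sorted record list. Output is identical to a
    single-partition run. A failed partition aborts the merge."""
    parts = partition_candidates(candidates, partitions)
    merged: list[GuideRecord] = []
    if threads > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            for result in pool.map(worker, parts):
                merged.extend(result)
    else:
        for part in parts:
            merged.extend(worker(part))
    merged.sort(key=lambda r: r.sort_key(seq_order))
    return merged
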