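"""Enumeration of gRNA off-target sites with mismatches and bulges.

A query is a spacer plus a PAM specification (primary motif, alternative
motifs, PAM side). Enumeration walks the FM-index as a simulated
reverse-prefix trie (see :mod:`guidex._kernel`) and returns every genomic
site, on either strand, whose PAM-adjacent window aligns to the spacer
within the mismatch and bulge budgets and whose PAM matches the primary or
an alternative motif. PAM degeneracy costs no mismatches (wildcard
semantics); the legacy semantics in which an alternative PAM consumes one
mismatch is available as a flag and always yields a subset.

A genomic locus reachable by several alignments (common with bulges) is
reported once, keyed by (sequence, strand, PAM start), with the alignment
minimizing (mismatches + bulges), ties broken by fewer bulges, then by
leftmost gap placement, then by leftmost mismatch placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import _kernel
from .fm_index import BASE_CODE, FMIndex, SAInterval
from .genome_io import Genome, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class PamSpec:
    """PAM motifs in IUPAC code; all motifs must share one length."""

    primary: str = "NGG"
    alternatives: tuple[str, ...] = ("NAG",)
    side: str = "3prime"

    def __post_init__(self):
        motifs = (self.primary, *self.alternatives)
        if not all(motifs):
            raise SearchError("PAM motifs must be non-empty")
        if len({len(m) for m in motifs}) != 1:
            raise SearchError("all PAM motifs must have the same length")
        for m in motifs:
            for ch in m:
                if ch not in IUPAC:
                    raise SearchError(f"invalid IUPAC code {ch!r} in PAM {m}")
        if self.side not in ("3prime", "5prime"):
            raise SearchError(f"invalid PAM side {self.side!r}")

    @property
    def length(self) -> int:
        return len(self.primary)

    def concrete_pams(self) -> tuple[list[str], set[str]]:
        """All concrete motifs (primary first) and the primary subset."""
        primary = set(expand_pam(self.primary))
        seen: list[str] = sorted(primary)
        for alt in self.alternatives:
            for m in sorted(expand_pam(alt)):
                if m not in primary and m not in seen:
                    seen.append(m)
        return seen, primary


@dataclass(frozen=True)
class SearchBudget:
    """Mismatch and bulge allowances for one search."""

    max_mismatches: int = 3
    max_rna_bulges: int = 0
    max_dna_bulges: int = 0

    def __post_init__(self):
        if min(self.max_mismatches, self.max_rna_bulges, self.max_dna_bulges) < 0:
            raise SearchError("budgets must be non-negative")

    def dominates(self, other: "SearchBudget") -> bool:
        return (
            self.max_mismatches >= other.max_mismatches
            and self.max_rna_bulges >= other.max_rna_bulges
            and self.max_dna_bulges >= other.max_dna_bulges
        )


@dataclass(frozen=True)
class GuideQuery:
    """A spacer (5'->3') with its PAM specification."""

    spacer: str
    pam: PamSpec = field(default_factory=PamSpec)
    declared_on_target: tuple[str, int, str] | None = None

    def __post_init__(self):
        if len(self.spacer) < 10:
            raise SearchError("spacer must be at least 10 nt")
        bad = set(self.spacer) - set("ACGT")
        if bad:
            raise SearchError(f"spacer contains non-ACGT characters: {sorted(bad)}")


@dataclass
class OffTarget:
    """One genomic site matched by a query, with alignment detail.

    Coordinates are 0-based half-open on the plus strand of the reference;
    mismatch positions are 1-based from the spacer 5' end.
    """

    sequence: str
    start: int
    end: int
    strand: str
    matched_protospacer: str
    matched_pam: str
    mismatches: list[tuple[int, str, str]]
    rna_bulges: int = 0
    dna_bulges: int = 0
    rna_bulge_positions: tuple[int, ...] = ()
    dna_bulge_gaps: tuple[int, ...] = ()
    pam_class: str = "primary"
    cfd: float | None = None

    @property
    def distance(self) -> int:
        """Mismatch count (bulges reported separately)."""
        return len(self.mismatches)

    @property
    def pam_start(self) -> int:
        return self.start - len(self.matched_pam) if self.strand == "-" else self.end

    def locus(self) -> tuple[str, str, int]:
        return (self.sequence, self.strand, self.pam_start)

    def mismatch_string(self) -> str:
        return ";".join(f"{p}:{sb}>{gb}" for p, sb, gb in self.mismatches)


def expand_pam(motif: str) -> list[str]:
    """All concrete ACGT motifs matching an IUPAC motif."""
    try:
        pools = [IUPAC[ch] for ch in motif]
    except KeyError as exc:
        raise SearchError(f"invalid IUPAC code in PAM motif {motif!r}") from exc
    return ["".join(p) for p in product(*pools)]


def iupac_match(motif: str, s: str) -> bool:
    return len(motif) == len(s) and all(b in IUPAC[m] for m, b in zip(motif, s))


def _codes(seq: str) -> np.ndarray:
    return np.array([BASE_CODE[c] for c in seq], dtype=np.int64)


_ALIGN_CAP_START = 4096


def _run_kernel(index: FMIndex, start: SAInterval, exp, spos, budget, suffix_exts, pam_idx):
    cap = _ALIGN_CAP_START
    while True:
        out = np.empty((cap, _kernel.HIT_COLS), dtype=np.int64)
        n = _kernel.trie_search(
            index.occ,
            index.C,
            start.low,
            start.high,
            exp,
            spos,
            budget.max_mismatches,
            budget.max_rna_bulges,
            budget.max_dna_bulges,
            suffix_exts,
            pam_idx,
            out,
        )
        if n <= cap:
            return out[:n]
        cap = max(cap * 2, n)


def _bits(mask: int) -> tuple[int, ...]:
    out = []
    b = 0
    while mask:
        if mask & 1:
            out.append(b)
        mask >>= 1
        b += 1
    return tuple(out)


def _alignment_sort_key(hit_row) -> tuple:
    mm, rb, db = int(hit_row[2]), int(hit_row[3]), int(hit_row[4])
    gaps = tuple(sorted(_bits(int(hit_row[6])) + _bits(int(hit_row[7]))))
    return (mm + rb + db, rb + db, gaps, _bits(int(hit_row[5])))


def enumerate_offtargets(
    index: FMIndex,
    query: GuideQuery,
    budget: SearchBudget = SearchBudget(),
    genome: Genome | None = None,
    legacy_pam_as_mismatch: bool = False,
    include_on_target: bool = False,
) -> list[OffTarget]:
    """All sites matching the query within the budget, both strands.

    ``genome`` supplies the sequence text used to report matched
    protospacers and mismatch bases; when omitted, those fields are
    reconstructed from the alignment (mismatched genomic bases are then
    only available if a genome is given, so passing it is recommended).
    The declared on-target, if any, is excluded unless
    ``include_on_target`` is set.
    """
    if query.pam.side != "3prime":
        raise SearchError("only 3'-side PAMs are supported by the search engine")
    spacer = query.spacer
    L = len(spacer)
    pams, primary_set = query.pam.concrete_pams()
    plen = query.pam.length

    raw: list[tuple[str, np.ndarray]] = []  # (strand, hit rows)

    # plus strand: PAM consumed first (exact), then spacer 3'->5'
    exp_plus = _codes(spacer[::-1])
    spos_plus = np.arange(L, 0, -1, dtype=np.int64)
    empty_ext = np.empty((0, plen), dtype=np.int64)
    for pidx, pam in enumerate(pams):
        start = index.interval_for(pam)
        if start.empty:
            continue
        hits = _run_kernel(index, start, exp_plus, spos_plus, budget, empty_ext, pidx)
        if len(hits):
            raw.append(("+", hits))

    # minus strand: complemented spacer 5'->3', then complemented PAMs
    exp_minus = _codes("".join(_COMP[c] for c in spacer))
    spos_minus = np.arange(1, L + 1, dtype=np.int64)
    pam_exts = np.array(
        [[BASE_CODE[_COMP[c]] for c in pam] for pam in pams], dtype=np.int64
    ).reshape(len(pams), plen)
    hits = _run_kernel(
        index, index.root(), exp_minus, spos_minus, budget, pam_exts, -1
    )
    if len(hits):
        raw.append(("-", hits))

    # resolve SA intervals to loci, dedup per (sequence, strand, pam start)
    best: dict[tuple[str, str, int], tuple[tuple, str, int, np.ndarray]] = {}
    for strand, rows in raw:
        for row in rows:
            key_align = _alignment_sort_key(row)
            wlen = L - int(row[3]) + int(row[4])
            for sarow in range(int(row[0]), int(row[1])):
                g = index.text_position(sarow)
                seq_name, local = index.global_to_local(g)
                if strand == "+":
                    pam_start = local + wlen
                else:
                    pam_start = local
                locus = (seq_name, strand, pam_start)
                prev = best.get(locus)
                if prev is None or key_align < prev[0]:
                    best[locus] = (key_align, seq_name, local, row.copy())

    seq_order = {name: i for i, name in enumerate(index.seq_names)}
    out: list[OffTarget] = []
    for (seq_name, strand, pam_start), (_, _, local, row) in best.items():
        wlen = L - int(row[3]) + int(row[4])
        if strand == "+":
            start, end = local, local + wlen
        else:
            start, end = local + plen, local + plen + wlen
        pam_idx = int(row[8])
        pam_str = pams[pam_idx]
        ot = _build_offtarget(
            genome, index, spacer, seq_name, start, end, strand, pam_str,
            int(row[2]), _bits(int(row[5])), _bits(int(row[6])), _bits(int(row[7])),
            primary_set,
        )
        if (
            not include_on_target
            and query.declared_on_target is not None
            and (seq_name, start, strand) == tuple(query.declared_on_target)
        ):
            continue
        out.append(ot)

    if legacy_pam_as_mismatch:
        out = [
            ot
            for ot in out
            if ot.pam_class == "primary"
            or ot.distance + 1 <= budget.max_mismatches
        ]

    out.sort(key=lambda o: (seq_order[o.sequence], o.start, o.strand))
    return out


def _build_offtarget(
    genome, index, spacer, seq_name, start, end, strand, pam_str,
    mm_count, mm_positions, rna_positions, dna_gaps, primary_set,
) -> OffTarget:
    L = len(spacer)
    if genome is not None:
        ref = genome[seq_name]
        window = ref[start:end]
        if strand == "+":
            pam_obs = ref[end : end + len(pam_str)]
            proto = window
        else:
            pam_obs = reverse_complement(ref[start - len(pam_str) : start])
            proto = reverse_complement(window)
    else:
        proto, pam_obs = "", pam_str

    mismatches: list[tuple[int, str, str]] = []
    if genome is not None:
        cursor = 0
        for pos in range(1, L + 1):
            if pos in rna_positions:
                continue
            for gap in dna_gaps:
                if gap == pos - 1:
                    cursor += 1
            gbase = proto[cursor]
            if gbase != spacer[pos - 1]:
                mismatches.append((pos, spacer[pos - 1], gbase))
            cursor += 1
        assert len(mismatches) == mm_count, "alignment reconstruction mismatch"
    else:
        mismatches = [(p, spacer[p - 1], "?") for p in mm_positions]

    pam_class = "primary" if pam_str in primary_set else "alternative"
    return OffTarget(
        sequence=seq_name,
        start=start,
        end=end,
        strand=strand,
        matched_protospacer=proto,
        matched_pam=pam_obs,
        mismatches=mismatches,
        rna_bulges=len(rna_positions),
        dna_bulges=len(dna_gaps),
        rna_bulge_positions=tuple(rna_positions),
        dna_bulge_gaps=tuple(dna_gaps),
        pam_class=pam_class,
    )


def find_perfect_sites(
    index: FMIndex,
    spacer: str,
    pam: PamSpec = PamSpec(),
    primary_only: bool = False,
    genome: Genome | None = None,
) -> list[OffTarget]:
    """All exact (0-mismatch, no-bulge) PAM-adjacent occurrences."""
    spec = PamSpec(pam.primary, (), pam.side) if primary_only else pam
    query = GuideQuery(spacer, spec)
    return enumerate_offtargets(
        index, query, SearchBudget(0, 0, 0), genome=genome, include_on_target=True
    )


def hamming_occurrences(index: FMIndex, seq: str, max_mm: int) -> int:
    """Number of genomic windows on either strand within Hamming distance
    ``max_mm`` of ``seq``, with no PAM requirement."""
    total = 0
    L = len(seq)
    budget = SearchBudget(max_mm, 0, 0)
    empty_ext = np.empty((0, 1), dtype=np.int64)
    for template in (seq[::-1], "".join(_COMP[c] for c in seq)):
        exp = _codes(template)
        spos = np.arange(L, dtype=np.int64) + 1  # reporting only; unused here
        hits = _run_kernel(index, index.root(), exp, spos, budget, empty_ext, -1)
        for row in hits:
            total += int(row[1]) - int(row[0])
    return total


def cut_site(site: OffTarget, pam_side: str = "3prime") -> tuple[str, int]:
    """Blunt-cut coordinate 3 nt upstream of the PAM (between spacer
    positions 17 and 18 for a 20-mer), as the 0-based reference index of
    the position-17 base, strand-aware."""
    if pam_side != "3prime":
        raise SearchError("cut-site rule undefined for this enzyme")
    if site.strand == "+":
        return site.sequence, site.end - 4
    return site.sequence, site.start + 3


def cut_site_coord(sequence: str, start: int, end: int, strand: str) -> tuple[str, int]:
    if strand == "+":
        return sequence, end - 4
    return sequence, start + 3
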