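"""Reference brute-force scanners.

These scan the genome text directly — no index — and serve as the
independent ground truth for the trie-traversal search: sliding-window
Hamming scans for mismatch-only search, and explicit banded-alignment
enumeration for bulged search. They share only the genome container and
the alignment conventions (bulges confined to the spacer interior, locus
keyed by PAM start, best alignment by (mismatches + bulges, bulges,
leftmost gaps, leftmost mismatches)) with the production path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .genome_io import Genome, reverse_complement
from .offtarget_search import IUPAC, OffTarget, PamSpec, SearchBudget, iupac_match

_ENC = np.full(256, 4, dtype=np.int8)  # N and anything else -> 4 (never matches)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_match_vector(codes: np.ndarray, starts: np.ndarray, motif: str) -> np.ndarray:
    """Boolean per start: does codes[start:start+len(motif)] match the motif?"""
    ok = np.ones(len(starts), dtype=bool)
    for j, m in enumerate(motif):
        allowed = [_ENC[ord(c)] for c in IUPAC[m]]
        col = codes[starts + j]
        ok &= np.isin(col, allowed)
    return ok


def scan_offtargets(
    genome: Genome,
    spacer: str,
    pam: PamSpec = PamSpec(),
    max_mm: int = 3,
    legacy_pam_as_mismatch: bool = False,
) -> list[OffTarget]:
    """Exhaustive Hamming scan over every PAM-adjacent window, both strands.

    Windows containing N never match. Returns sites sorted like the
    production search.
    """
    L, plen = len(spacer), pam.length
    pams, primary = pam.concrete_pams()
    out: list[OffTarget] = []
    for seq_name, ref in genome.sequences.items():
        n = len(ref)
        if n < L + plen:
            continue
        for strand in "+-":
            text = ref if strand == "+" else reverse_complement(ref)
            codes = _encode(text)
            win = np.lib.stride_tricks.sliding_window_view(codes, L)
            starts = np.arange(n - L - plen + 1)
            spacer_codes = _encode(spacer)
            mm = (win[starts] != spacer_codes).sum(axis=1)
            has_n = (win[starts] == 4).any(axis=1)
            cand = np.zeros(len(starts), dtype=bool)
            pam_of = np.full(len(starts), -1, dtype=np.int64)
            pam_starts = starts + L
            pam_has_n = np.lib.stride_tricks.sliding_window_view(codes, plen)[
                pam_starts
            ]
            pam_ok_any = ~(pam_has_n == 4).any(axis=1)
            for pidx, motif in enumerate(pams):
                hit = _pam_match_vector(codes, pam_starts, motif) & pam_ok_any
                newly = hit & (pam_of < 0)
                pam_of[newly] = pidx
                cand |= hit
            keep = cand & ~has_n & (mm <= max_mm)
            for p in np.nonzero(keep)[0]:
                proto = text[p : p + L]
                pam_obs = text[p + L : p + L + plen]
                mismatches = [
                    (i + 1, spacer[i], proto[i])
                    for i in range(L)
                    if proto[i] != spacer[i]
                ]
                if strand == "+":
                    start, end = int(p), int(p + L)
                else:
                    start, end = n - int(p) - L, n - int(p)
                pam_class = "primary" if pams[pam_of[p]] in primary else "alternative"
                if legacy_pam_as_mismatch and pam_class == "alternative":
                    if len(mismatches) + 1 > max_mm:
                        continue
                out.append(
                    OffTarget(
                        sequence=seq_name,
                        start=start,
                        end=end,
                        strand=strand,
                        matched_protospacer=proto,
                        matched_pam=pam_obs,
                        mismatches=mismatches,
                        pam_class=pam_class,
                    )
                )
    order = {name: i for i, name in enumerate(genome.sequences)}
    out.sort(key=lambda o: (order[o.sequence], o.start, o.strand))
    return out


def _alignments(L: int, budget: SearchBudget):
    """All (rna_positions, dna_gaps) gap patterns within budget.

    RNA bulges may sit at spacer positions 2..L-1; DNA bulges at gaps
    1..L-1 (between spacer positions g and g+1). The all-empty pattern is
    included.
    """
    rna_pool = range(2, L)
    dna_pool = range(1, L)
    for nr in range(budget.max_rna_bulges + 1):
        for rna in combinations(rna_pool, nr):
            for nd in range(budget.max_dna_bulges + 1):
                for dna in combinations(dna_pool, nd):
                    yield rna, dna


def scan_offtargets_bulged(
    genome: Genome,
    spacer: str,
    pam: PamSpec = PamSpec(),
    budget: SearchBudget = SearchBudget(2, 1, 1),
) -> list[OffTarget]:
    """Banded-alignment enumeration oracle for bulged off-target search.

    For every PAM-matching position on both strands and every gap pattern
    within the bulge budgets, aligns the spacer to the genomic window and
    keeps loci whose best alignment is within the mismatch budget. Each
    locus (sequence, strand, PAM start) is reported once with its best
    alignment under the canonical order.
    """
    L, plen = len(spacer), pam.length
    pams, primary = pam.concrete_pams()
    best: dict[tuple[str, str, int], tuple[tuple, OffTarget]] = {}
    patterns = list(_alignments(L, budget))
    for seq_name, ref in genome.sequences.items():
        n = len(ref)
        for strand in "+-":
            text = ref if strand == "+" else reverse_complement(ref)
            codes = _encode(text)
            # candidate PAM positions (vectorized), excluding N-containing PAMs
            pos_all = np.arange(n - plen + 1)
            pam_ok = np.zeros(len(pos_all), dtype=bool)
            for motif in pams:
                pam_ok |= _pam_match_vector(codes, pos_all, motif)
            pam_positions = pos_all[pam_ok]
            spacer_codes = _encode(spacer)
            candidates: list[tuple[int, tuple, tuple]] = []
            for rna, dna in patterns:
                wlen = L - len(rna) + len(dna)
                sites = pam_positions[pam_positions >= wlen]
                if len(sites) == 0:
                    continue
                # offset of each aligned spacer position within the window
                offsets, expected = [], []
                cursor = 0
                for pos in range(1, L + 1):
                    if pos in rna:
                        continue
                    if pos - 1 in dna:
                        cursor += 1
                    offsets.append(cursor)
                    expected.append(spacer_codes[pos - 1])
                    cursor += 1
                idx = sites[:, None] - wlen + np.asarray(offsets)[None, :]
                got = codes[idx]
                mm = (got != np.asarray(expected)[None, :]).sum(axis=1)
                # windows containing N never match
                winidx = sites[:, None] - wlen + np.arange(wlen)[None, :]
                has_n = (codes[winidx] == 4).any(axis=1)
                hit = (~has_n) & (mm <= budget.max_mismatches)
                for pam_pos in sites[hit]:
                    candidates.append((int(pam_pos), rna, dna))
            for pam_pos, rna, dna in candidates:
                pam_obs = text[pam_pos : pam_pos + plen]
                matched = next(m for m in pams if iupac_match(m, pam_obs))
                wlen = L - len(rna) + len(dna)
                wstart = pam_pos - wlen
                window = text[wstart:pam_pos]
                mismatches = []
                cursor = 0
                for pos in range(1, L + 1):
                    if pos in rna:
                        continue
                    if pos - 1 in dna:
                        cursor += 1
                    if window[cursor] != spacer[pos - 1]:
                        mismatches.append((pos, spacer[pos - 1], window[cursor]))
                    cursor += 1
                nb = len(rna) + len(dna)
                key = (
                    len(mismatches) + nb,
                    nb,
                    tuple(sorted(rna + dna)),
                    tuple(p for p, _, _ in mismatches),
                )
                if strand == "+":
                    start, end = wstart, pam_pos
                    pam_ref_start = pam_pos
                else:
                    start, end = n - pam_pos, n - wstart
                    pam_ref_start = n - pam_pos - plen
                locus = (seq_name, strand, pam_ref_start)
                prev = best.get(locus)
                if prev is None or key < prev[0]:
                    best[locus] = (
                        key,
                        OffTarget(
                            sequence=seq_name,
                            start=start,
                            end=end,
                            strand=strand,
                            matched_protospacer=window,
                            matched_pam=pam_obs,
                            mismatches=mismatches,
                            rna_bulges=len(rna),
                            dna_bulges=len(dna),
                            rna_bulge_positions=tuple(rna),
                            dna_bulge_gaps=tuple(dna),
                            pam_class="primary" if matched in primary else "alternative",
                        ),
                    )
    order = {name: i for i, name in enumerate(genome.sequences)}
    sites = [ot for _, ot in best.values()]
    sites.sort(key=lambda o: (order[o.sequence], o.start, o.strand))
    return sites


def hamming_window_count(genome: Genome, seq: str, max_mm: int) -> int:
    """Windows on either strand within Hamming distance max_mm (PAM-free)."""
    L = len(seq)
    total = 0
    pat = _encode(seq)
    for ref in genome.sequences.values():
        if len(ref) < L:
            continue
        for text in (ref, reverse_complement(ref)):
            win = np.lib.stride_tricks.sliding_window_view(_encode(text), L)
            mm = (win != pat).sum(axis=1)
            has_n = (win == 4).any(axis=1)
            total += int((~has_n & (mm <= max_mm)).sum())
    return total
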