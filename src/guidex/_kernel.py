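"""Numba kernel for the simulated reverse-prefix trie traversal.

The traversal walks suffix-array intervals of the FM-index as if descending
a trie of reversed text prefixes. Consumption order is backward-search
order (symbols are prepended), so the caller encodes its template — spacer
and PAM, strand-resolved — in consumption order:

* plus strand: the concrete PAM is consumed before the kernel is entered
  (its exact backward-search interval is the kernel's start state), then
  the kernel consumes the spacer 3'->5';
* minus strand: the kernel consumes the complemented spacer 5'->3' from the
  root, then extends by each complemented concrete PAM (``suffix_exts``).

Moves at each state: consume one genomic symbol (mismatch cost 1 when it
differs from the expected template symbol), an RNA bulge (template advances
with no genomic symbol), or a DNA bulge (genomic symbol consumed with no
template advance). Bulges are confined to the interior of the spacer:
never in the PAM, never at the PAM-adjacent spacer position, never at the
PAM-distal terminus. Branches with an empty interval or exhausted budget
are pruned.

Hit rows: (lo, hi, mm, rna, dna, mm_mask, rna_mask, dna_mask, pam_idx)
where masks are bitmasks over 1-based spacer positions / gap indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

HIT_COLS = 9


@njit(cache=True)
def trie_search(
    occ,  # int64[n+1, 6] cumulative BWT symbol counts
    C,  # int64[6]
    start_lo,
    start_hi,
    exp,  # int64[L] expected symbol codes, consumption order
    spos,  # int64[L] 1-based spacer position per consumption index
    k,  # max mismatches
    max_rna,
    max_dna,
    suffix_exts,  # int64[n_ext, plen] exact extensions after the template
    pam_idx_const,  # pam index to report when n_ext == 0
    out,  # int64[capacity, 9]
):
    """Depth-first traversal; returns total hits (may exceed capacity)."""
    L = exp.shape[0]
    n_ext = suffix_exts.shape[0]
    capacity = out.shape[0]
    n_hits = 0

    # explicit stack: lo, hi, t, mm, rb, db, mm_mask, rna_mask, dna_mask
    stack = np.empty((4096, 9), dtype=np.int64)
    top = 0
    stack[top, 0] = start_lo
    stack[top, 1] = start_hi
    stack[top, 2] = 0
    for j in range(3, 9):
        stack[top, j] = 0
    top += 1

    while top > 0:
        top -= 1
        lo = stack[top, 0]
        hi = stack[top, 1]
        t = stack[top, 2]
        mm = stack[top, 3]
        rb = stack[top, 4]
        db = stack[top, 5]
        mm_mask = stack[top, 6]
        rna_mask = stack[top, 7]
        dna_mask = stack[top, 8]

        if t == L:
            if n_ext == 0:
                if n_hits < capacity:
                    out[n_hits, 0] = lo
                    out[n_hits, 1] = hi
                    out[n_hits, 2] = mm
                    out[n_hits, 3] = rb
                    out[n_hits, 4] = db
                    out[n_hits, 5] = mm_mask
                    out[n_hits, 6] = rna_mask
                    out[n_hits, 7] = dna_mask
                    out[n_hits, 8] = pam_idx_const
                n_hits += 1
            else:
                for e in range(n_ext):
                    elo, ehi = lo, hi
                    ok = True
                    for j in range(suffix_exts.shape[1]):
                        c = suffix_exts[e, j]
                        elo = C[c] + occ[elo, c]
                        ehi = C[c] + occ[ehi, c]
                        if elo >= ehi:
                            ok = False
                            break
                    if ok:
                        if n_hits < capacity:
                            out[n_hits, 0] = elo
                            out[n_hits, 1] = ehi
                            out[n_hits, 2] = mm
                            out[n_hits, 3] = rb
                            out[n_hits, 4] = db
                            out[n_hits, 5] = mm_mask
                            out[n_hits, 6] = rna_mask
                            out[n_hits, 7] = dna_mask
                            out[n_hits, 8] = e
                        n_hits += 1
            continue

        if top + 9 >= stack.shape[0]:
            # grow the stack (rare: bounded by depth x branching)
            new_stack = np.empty((stack.shape[0] * 2, 9), dtype=np.int64)
            new_stack[: stack.shape[0]] = stack
            stack = new_stack

        # DNA bulge: consume an extra genomic symbol, template stays.
        # Interior only: at least one spacer symbol consumed and one left.
        if db < max_dna and 1 <= t <= L - 1:
            gap = spos[t - 1] if spos[t - 1] < spos[t] else spos[t]
            for c in range(2, 6):
                nlo = C[c] + occ[lo, c]
                nhi = C[c] + occ[hi, c]
                if nlo < nhi:
                    stack[top, 0] = nlo
                    stack[top, 1] = nhi
                    stack[top, 2] = t
                    stack[top, 3] = mm
                    stack[top, 4] = rb
                    stack[top, 5] = db + 1
                    stack[top, 6] = mm_mask
                    stack[top, 7] = rna_mask
                    stack[top, 8] = dna_mask | (1 << gap)
                    top += 1

        # RNA bulge: skip a spacer position (interior, not PAM-adjacent).
        if rb < max_rna and 1 <= t <= L - 2:
            stack[top, 0] = lo
            stack[top, 1] = hi
            stack[top, 2] = t + 1
            stack[top, 3] = mm
            stack[top, 4] = rb + 1
            stack[top, 5] = db
            stack[top, 6] = mm_mask
            stack[top, 7] = rna_mask | (1 << spos[t])
            stack[top, 8] = dna_mask
            top += 1

        # consume one genomic symbol (match or mismatch)
        for c in range(2, 6):
            cost = 0 if c == exp[t] else 1
            if mm + cost > k:
                continue
            nlo = C[c] + occ[lo, c]
            nhi = C[c] + occ[hi, c]
            if nlo < nhi:
                stack[top, 0] = nlo
                stack[top, 1] = nhi
                stack[top, 2] = t + 1
                stack[top, 3] = mm + cost
                stack[top, 4] = rb
                stack[top, 5] = db
                stack[top, 6] = mm_mask | ((1 << spos[t]) if cost else 0)
                stack[top, 7] = rna_mask
                stack[top, 8] = dna_mask
                top += 1

    return n_hits
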