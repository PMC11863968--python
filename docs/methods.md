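# Methods

## Genome representation and coordinates

Genomes are loaded from FASTA into uppercase `{A,C,G,T,N}` strings; every
other IUPAC ambiguity code collapses to `N`, and soft-masked (lowercase)
bases are uppercased and treated as targetable — repeat avoidance is an
explicit interval filter, not an alphabet rule. All internal coordinates
are 0-based half-open; the only conversions happen at the parsing and
emission boundaries (GTF/GFF 1-based inclusive in, SAM 1-based out), so
there is a single place for each off-by-one to live. For indexing, the
sequences are concatenated with one separator symbol between them and a
terminator at the end; the separator is outside the search alphabet, so a
match can never span a sequence boundary.

## The index

The FM-index stores the Burrows–Wheeler transform of the concatenated
text over the 6-symbol alphabet `{terminator, separator, A, C, G, T}`,
a cumulative occurrence table (rank in O(1) by direct lookup), the
C-array, and suffix-array samples at a configurable rate (default 16;
any rate produces identical results, as tested). `N` bases are replaced
by the separator code at index time, which implements the "N never
matches" contract with no per-query checks. The suffix array is built by
numpy prefix doubling — O(n log² n) with vectorized sorts — which is
worst-case safe on repetitive input and entirely adequate for the
megabase-scale genomes this package targets; an induced-sorting
construction would only matter well beyond that scale. Only the forward
text is indexed: minus-strand search queries the reverse complement of
the pattern and maps coordinates back, halving index size.

Serialization is a single file: magic bytes, a versioned JSON header,
then length-prefixed raw arrays. The layout is deterministic, so two
builds of the same genome are byte-identical; loading a corrupted or
version-mismatched file fails atomically.

## Off-target enumeration

A query is a spacer plus a PAM specification (primary motif, alternative
motifs, 3'-side). Enumeration is a depth-first traversal of suffix-array
intervals — the implicit trie of backward-search states. Because
backward search prepends symbols, the traversal consumes the site text
right-to-left: on the plus strand the concrete PAM is matched first
(exactly), then the spacer 3'→5'; on the minus strand the complemented
spacer is consumed 5'→3' and the complemented PAMs are applied as exact
suffix extensions at the leaves. At each state the traversal tries all
four bases (a non-expected base costs one mismatch), an RNA bulge
(spacer position skipped), or a DNA bulge (extra genomic base consumed),
pruning any branch with an empty interval or exhausted budget. The
kernel is a numba-compiled iterative DFS; the surrounding bookkeeping
(coordinate recovery via LF-walks to suffix-array samples, alignment
reconstruction, deduplication, sorting) is ordinary Python/numpy.

PAM handling follows wildcard semantics: degeneracy within any allowed
motif costs no mismatches, so an `NAG` site with `k` spacer mismatches is
reported at distance `k`. The legacy convention, where an alternative
PAM consumes one mismatch, is a post-filter (alternative-PAM sites kept
only when `mismatches + 1 ≤ k`), which makes the subset relationship
hold by construction; tests still assert it, including strict inclusion
on planted fixtures.

Bulge placement needed a convention the alignment literature does not
fix: bulges are forbidden inside the PAM, at the PAM-adjacent spacer
position (bulge-search tools conventionally anchor the PAM), and at the
PAM-distal terminus (a terminal gap is degenerate with an ungapped
window shifted by one). A genomic locus reachable by several alignments
— common with bulges — is reported once, keyed by (sequence, strand, PAM
start), with the alignment minimizing (mismatches + bulges), ties broken
by fewer bulges, then leftmost gap placement, then leftmost mismatch
placement. The brute-force oracles implement the identical conventions,
so set equality is exact.

## Reference oracles

`guidex.bruteforce` contains two scanners that share nothing with the
index path beyond the genome container: a vectorized sliding-window
Hamming scan over every PAM-adjacent window on both strands, and a
banded-alignment enumerator that tries every gap pattern within the
bulge budgets at every PAM-matching position. They are the ground truth
for the acceptance tests and for planted-fixture verification, and are
deliberately slow-but-obvious rather than clever.

## Scoring

CFD is the product of one penalty per spacer/protospacer mismatch —
keyed by 1-based spacer position (1 = 5'-distal) and the base pair — and
a penalty for the concrete PAM trinucleotide. Both CFD and the
aggregated specificity `1/(1 + Σ CFD)` are defined only for 20-nt
spacers, because the underlying empirical measurements were; shorter or
longer guides get no score rather than an approximation. Bulged sites
carry no CFD definition: they are reported by the search but excluded
from scoring. The aggregation uses exact (`math.fsum`) accumulation so
specificity is bit-identical under off-target reordering.

The packaged penalty table is **synthetic**: penalties decay linearly
from 0.964 (position 1) to 0.28 (position 20), transversions are scaled
by 0.65 relative to transitions, `NGG` PAMs score 1.0 and `NAG` 0.25.
This reproduces the qualitative structure of the empirical tables
(PAM-proximal "seed" mismatches hurt most) and satisfies every invariant
the code enforces, but absolute specificity values on real genomes
require substituting an empirically derived table via
`load_cfd_table(path)`. Cutting efficiency is a pluggable provider
(`EfficiencyModel`) in [0, 1] — a TSV of per-spacer scores, a callable
wrapping a regression model, or the seeded-hash provider used by
fixtures; no efficiency model is trained here.

When a guide's intended target is not declared, specificity excludes an
implied on-target: the first 0-mismatch primary-PAM site in coordinate
order, if any. Further perfect sites count as off-targets with CFD 1,
which is what penalizes multi-mapping guides.

## Guide databases

Database construction enumerates every primary-PAM candidate window,
drops candidates whose spacer has more than one perfect primary-PAM
occurrence genome-wide, annotates survivors with all off-targets within
the budget (alternative PAMs included; perfect alternative-PAM sites
appear as distance-0 off-targets), and scores them. Output is sorted
SAM: POS 1-based, FLAG 16 for minus-strand guides, SEQ in
reference-forward orientation, specificity and efficiency in `cs`/`ds`
float tags, and the off-target list in an `of` hex tag. The hex layout
is one version byte (0x01) followed by 9 bytes per off-target: a
little-endian uint64 of `global_coordinate << 1 | strand_bit` and a
uint8 mismatch distance. An empty list encodes as the empty string.
Partitioned runs split the sorted candidate list round-robin and merge;
the output is identical to a single-partition run, which is the tested
contract that makes cluster-scale parallelism safe.

## Library design

The filter cascade runs in a fixed order, each stage reported: (1) drop
guides with any additional 0- or 1-mismatch occurrence (primary or
alternative PAM, the same scope the database uses); (2) keep guides
whose cut site — 3 nt upstream of the PAM, between spacer positions 17
and 18 — lies in a CDS; (3) efficiency ≥ 0.25; (4) specificity ≥ 0.20;
(5) spacer G+C within [0.20, 0.80], inclusive bounds surviving, computed
over the spacer only since that is the synthesized sequence; (6) no
monopolymer run longer than 3. Per gene, up to six guides are kept by
`Score(g) = min{Spec(g), Spec(g'), 1.25·Eff(g)}`, where Spec(g') comes
from a fresh off-target search of the 5'-G-substituted spacer (identical
to Spec(g) when the spacer already starts with G). Ties break by score,
then specificity, then coordinate. A guide whose cut site lies in CDS of
several genes competes for each of them. Non-targeting controls are
random 20-mers with zero genomic windows within Hamming distance 3 on
either strand (rejection-sampled under a seed, verified against the
index); safe-targeting controls cut inside supplied safe-harbor
intervals, pass the applicable cascade stages, and rank by specificity.

## Allele-specific design

Strain variants (SNPs and small indels, VCF in) are applied left to
right to build the second allele's pseudo-genome plus a piecewise-linear
coordinate map (positions inside deletions are unmappable). Databases
are built per genome; a guide is allele-specific when its spacer has
zero perfect PAM-adjacent occurrences in the other genome — checked
under primary *and* alternative PAMs, since an NAG-adjacent perfect
protospacer in the other allele can still cut. Near-perfect cross-genome
matches are not excluded, only reported in the two-genome off-target
summaries: discrimination is defined by perfect-match absence, and the
efficiency difference is the biology. Discrimination is classified as
`pam_variant` (variant overlaps the PAM window), `protospacer_variant`,
or `structural` (the fallback when no small variant overlaps, e.g.
guides inside one-allele insertions). The high-confidence cascade —
drop guides annotated with heterozygous variants, no 2-mismatch
off-targets in either genome, at most three 3-mismatch off-targets,
efficiency in the top quartile of the surviving set, cut site ≥ 200 bp
from annotated repeats — mirrors a sensible validation-candidate
selection and is fully parameterized. Gene annotation tags a guide with
the gene whose exon contains its cut site, choosing the
lexicographically smallest id among several candidates so the output is
deterministic.

## Synthetic data

The fixture generator is first-class, tested code. Random genomes are
i.i.d. draws with a target GC fraction; annotations are evenly spaced
non-overlapping genes with nested exon/CDS features; diploid simulation
draws SNPs (default rate 0.002/bp) and 1–3 bp indels (0.0002/bp) with
rejection of overlaps — rates of the order observed between inbred
mouse strains, where allele-specific design is practiced. Planted-site
fixtures write mutated spacer+PAM copies (transition substitutions, so
CFD contributions are predictable) at requested positions and take their
truth tables from a brute-force re-scan of the mutated genome, so
accidental background matches in the random filler are folded into the
truth rather than breaking oracles. The engineered library-cascade
fixture builds twelve guides of which exactly one violates each cascade
stage (a 1-mismatch duplicate, an extragenic cut site, efficiency 0.10,
six planted 2-mismatch off-targets driving specificity to ~0.16, 90%
G+C, an AAAA run), generated deterministically rather than checked in
as files.

What passing these tests shows — and does not. The oracles prove the
search is exhaustive and the pipelines deterministic on genomes whose
statistics are i.i.d.; real genomes add repeat families (handled in
principle by the same index, but making uniqueness filters far more
consequential), soft-masking conventions, and empirically calibrated
CFD/efficiency scores that the synthetic stand-ins do not provide.
Absolute specificity values and library contents on real genomes
therefore depend on the substituted score tables and annotation
versions; the structural guarantees (completeness, dedup, determinism,
cascade order) carry over unchanged.

## Problem sizes and numerical choices

Tests run on genomes of 10–100 kb with mismatch budgets up to 4 and
bulge budgets up to 1+1 — sizes chosen so the brute-force oracles stay
tractable while every code path (multi-sequence genomes, both strands,
all budgets, partitioned runs) is exercised; the index and traversal
themselves scale to megabases on a laptop. Determinism is contractual
everywhere: all randomness flows through seeded generators, parallelism
exists only across candidate partitions, and ties are always broken by
explicit keys. Degenerate inputs (empty candidate lists, empty
off-target sets, genes without guides, genomes smaller than one window)
return empty results or reports rather than raising, while contract
violations (ref-allele mismatches, overlapping variants, malformed
tables, version-mismatched indexes) fail hard with located messages.

## Known limitations

The cut-site rule is the blunt 3-nt-upstream convention for 3'-PAM
nucleases; 5'-PAM enzymes (Cas12a) are accepted by the PAM model but the
cut-site-dependent steps refuse them rather than guessing. The BWT is
stored uncompressed (no wavelet-tree rank over compressed text), trading
memory for simplicity — fine up to tens of megabases, not for mammalian
whole genomes in one piece; per-chromosome indexing is the practical
route there. Guides overlapping deletion breakpoints classify as
`structural` rather than being traced through the rearrangement. The
packaged CFD table is synthetic, as discussed above.
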