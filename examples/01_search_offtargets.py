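"""Enumerate gRNA off-targets in a synthetic genome.

Builds a 50 kb random genome with planted off-target sites (an exact
match, mismatched copies and a bulged copy), indexes it, and runs the
trie-traversal search with mismatch and bulge budgets.
"""

from guidex import (
    GuideQuery,
    PamSpec,
    PlantedSite,
    SearchBudget,
    build_index,
    enumerate_offtargets,
    plant_sites,
    random_genome,
)

SPACER = "GTTCAGCTAAGCTACGTACG"

base = random_genome(50_000, gc=0.45, seed=7)
genome, truth = plant_sites(
    base,
    SPACER,
    PamSpec(),  # NGG primary, NAG alternative
    [
        PlantedSite(5_000, "+"),                      # exact on-target
        PlantedSite(15_000, "+", mismatches=2),       # 2-mismatch site
        PlantedSite(25_000, "-", mismatches=1, pam="TAG"),  # NAG site, minus strand
        PlantedSite(35_000, "+", rna_bulge_at=8),     # RNA-bulged site
    ],
    SearchBudget(3, 1, 1),
    seed=8,
)

index = build_index(genome)
hits = enumerate_offtargets(
    index,
    GuideQuery(SPACER),
    SearchBudget(max_mismatches=3, max_rna_bulges=1, max_dna_bulges=1),
    genome=genome,
    include_on_target=True,
)

print(f"spacer {SPACER} (PAM NGG, alternative NAG)")
print(f"{len(hits)} site(s) within 3 mismatches + 1 RNA / 1 DNA bulge:\n")
print("chrom  start  strand pam  class       mm  bulges  mismatches")
for o in hits:
    print(
        f"{o.sequence:6} {o.start:6} {o.strand:5} {o.matched_pam:4} "
        f"{o.pam_class:11} {o.distance:2}  r{o.rna_bulges}/d{o.dna_bulges}   "
        f"{o.mismatch_string() or '-'}"
    )
print(
    "\nEach line is one genomic locus the guide can engage; 'mm' counts "
    "spacer/protospacer mismatches and bulges are unpaired bases in the "
    "RNA (r) or DNA (d) strand of the alignment."
)
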