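"""CFD-based off-target scoring and specificity aggregation.

The cutting-frequency-determination (CFD) model assigns each off-target a
cleavage likelihood in [0, 1]: the product of one empirical penalty per
spacer/protospacer mismatch (keyed by 1-based spacer position and the
spacer/genomic base pair) and one penalty for the concrete PAM observed at
the site. A perfect primary-PAM match scores 1. Per-guide specificity
aggregates CFD over all off-targets:

    Specificity(g) = 1 / (1 + sum over off-targets o of CFD(o, g))

so 1 means no predicted off-targets and values near 0 mean many or closely
matching ones. Both CFD and specificity are defined only for 20-nt
spacers, because the empirical penalties were measured for that length.

The packaged default penalty table (``data/cfd_synthetic.tsv``) is a
synthetic stand-in with the empirically motivated structure — penalties
decay toward the PAM-proximal end, transversions are penalised more than
transitions, NGG PAMs score 1 — and is user-replaceable by any file in the
same format with genuine empirical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping

from .offtarget_search import GuideQuery, OffTarget

SPACER_LENGTH = 20
BASES = "ACGT"


class ScoringError(ValueError):
    pass


@dataclass
class CFDTable:
    """Mismatch penalties keyed by (position 1..20, spacer base, genomic
    base) and PAM penalties keyed by concrete PAM trinucleotide."""

    mismatch_penalty: dict[tuple[int, str, str], float]
    pam_penalty: dict[str, float]

    def validate(self) -> None:
        for pos in range(1, SPACER_LENGTH + 1):
            gaps = [
                (pos, r, d)
                for r in BASES
                for d in BASES
                if (pos, r, d) not in self.mismatch_penalty
            ]
            if gaps:
                raise ScoringError(f"CFD table is missing entries: {gaps[:5]} ...")
        for key, val in self.mismatch_penalty.items():
            pos, r, d = key
            if not 0.0 <= val <= 1.0:
                raise ScoringError(f"CFD penalty out of [0,1] at {key}: {val}")
            if r == d and val != 1.0:
                raise ScoringError(f"matching-base penalty must be 1 at {key}")
        for pam, val in self.pam_penalty.items():
            if not 0.0 <= val <= 1.0:
                raise ScoringError(f"PAM penalty out of [0,1] for {pam}: {val}")
        for base in BASES:
            if self.pam_penalty.get(base + "GG") != 1.0:
                raise ScoringError(f"PAM penalty for {base}GG must be 1")


def load_cfd_table(path=None) -> CFDTable:
    """Load a penalty table; defaults to the packaged synthetic table.

    Format: tab-delimited; ``#`` comment lines ignored; 4-field rows are
    mismatch entries (position, spacer base, genomic base, penalty) and
    2-field rows are PAM entries (trinucleotide, penalty).
    """
    if path is None:
        ref = resources.files("guidex").joinpath("data/cfd_synthetic.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mismatch: dict[tuple[int, str, str], float] = {}
    pam: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 4:
            pos, r, d, val = fields
            mismatch[(int(pos), r, d)] = float(val)
        elif len(fields) == 2:
            pam[fields[0]] = float(fields[1])
        else:
            raise ScoringError(f"CFD table line {lineno}: expected 2 or 4 fields")
    table = CFDTable(mismatch, pam)
    table.validate()
    return table


def cfd_score(query: GuideQuery, off: OffTarget, table: CFDTable) -> float:
    """Product of per-mismatch penalties times the PAM penalty.

    Defined only for bulge-free alignments of 20-nt spacers.
    """
    if len(query.spacer) != SPACER_LENGTH:
        raise ScoringError("CFD is defined only for length-20 spacers")
    if off.rna_bulges or off.dna_bulges:
        raise ScoringError("CFD is undefined for bulged off-targets")
    pam = off.matched_pam
    if pam not in table.pam_penalty:
        raise ScoringError(f"no PAM penalty for {pam!r}")
    score = table.pam_penalty[pam]
    for pos, spacer_base, genomic_base in off.mismatches:
        score *= table.mismatch_penalty[(pos, spacer_base, genomic_base)]
    return score


def aggregate_specificity(cfd_values: Iterable[float]) -> float:
    """1 / (1 + sum of CFD values); 1.0 for an empty collection.

    The sum uses exact (fsum) accumulation so the result is independent
    of off-target ordering down to the last bit."""
    return 1.0 / (1.0 + math.fsum(cfd_values))


@dataclass
class SpecificityResult:
    specificity: float
    n_offtargets_by_distance: dict[int, int]
    cfd_sum: float


def specificity(
    query: GuideQuery,
    offtargets: list[OffTarget],
    table: CFDTable,
    exclude_bulged: bool = True,
) -> SpecificityResult:
    """Aggregate CFD over the off-target list into the specificity score.

    The caller is responsible for excluding the designated on-target.
    Bulged sites carry no CFD definition: they are dropped when
    ``exclude_bulged`` is set and are an error otherwise.
    """
    if len(query.spacer) != SPACER_LENGTH:
        raise ScoringError("specificity is defined only for length-20 spacers")
    scored = []
    for off in offtargets:
        if off.rna_bulges or off.dna_bulges:
            if exclude_bulged:
                continue
            raise ScoringError(
                "bulged off-target passed to specificity; filter upstream"
            )
        scored.append(off)
    cfd_sum = sum(cfd_score(query, off, table) for off in scored)
    by_distance: dict[int, int] = {}
    for off in scored:
        by_distance[off.distance] = by_distance.get(off.distance, 0) + 1
    return SpecificityResult(
        specificity=aggregate_specificity(
            cfd_score(query, off, table) for off in scored
        ),
        n_offtargets_by_distance=by_distance,
        cfd_sum=float(cfd_sum),
    )


def specificity_with_implied_on_target(
    index,
    spacer: str,
    pam,
    budget,
    table: CFDTable,
    genome=None,
) -> SpecificityResult:
    """Specificity from a fresh off-target search, excluding the implied
    on-target: if at least one 0-mismatch primary-PAM site exists, the
    first in coordinate order is treated as the intended target and
    excluded; every other site (including further perfect matches, which
    penalise multi-mapping guides) contributes its CFD."""
    from .offtarget_search import GuideQuery, enumerate_offtargets

    query = GuideQuery(spacer, pam)
    offs = enumerate_offtargets(
        index, query, budget, genome=genome, include_on_target=True
    )
    perfect_primary = [
        o
        for o in offs
        if o.distance == 0
        and not (o.rna_bulges or o.dna_bulges)
        and o.pam_class == "primary"
    ]
    implied = perfect_primary[0] if perfect_primary else None
    remaining = [o for o in offs if o is not implied]
    return specificity(query, remaining, table)


def five_prime_g_variant(spacer: str) -> str:
    """The spacer with its 5'-most nucleotide replaced by G (g')."""
    if not spacer:
        raise ScoringError("empty spacer")
    return "G" + spacer[1:]


def library_score(
    spec_g: float, spec_gprime: float, efficiency: float, weight: float = 1.25
) -> float:
    """min{Specificity(g), Specificity(g'), weight * CuttingEfficiency(g)}.

    The weight (default 1.25) lets a highly efficient guide compensate for
    moderate specificity when ranking guides within a gene.
    """
    return min(spec_g, spec_gprime, weight * efficiency)


class EfficiencyModel:
    """Pluggable cutting-efficiency provider: spacer -> score in [0, 1].

    Rule-Set-2-style regression models can be wired in by wrapping their
    predict function; fixtures use a table- or hash-based provider.
    """

    def __init__(self, fn: Callable[[str], float], name: str = "custom"):
        self._fn = fn
        self.name = name

    def __call__(self, spacer: str) -> float:
        val = float(self._fn(spacer))
        if not 0.0 <= val <= 1.0:
            raise ScoringError(f"efficiency {val} outside [0,1] for {spacer}")
        return val

    @classmethod
    def from_table(cls, table: Mapping[str, float], default: float | None = None,
                   name: str = "table") -> "EfficiencyModel":
        def fn(spacer: str) -> float:
            if spacer in table:
                return table[spacer]
            if default is not None:
                return default
            raise ScoringError(f"no efficiency entry for spacer {spacer}")

        return cls(fn, name=name)

    @classmethod
    def from_tsv(cls, path: str, default: float | None = None) -> "EfficiencyModel":
        """Two-column TSV: spacer, efficiency."""
        table: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                spacer, val = line.split("\t")[:2]
                table[spacer] = float(val)
        return cls.from_table(table, default=default, name=path)

    @classmethod
    def seeded_hash(cls, seed: int = 0, name: str = "hash") -> "EfficiencyModel":
        """Deterministic pseudo-efficiency in [0,1] per spacer; fixture use."""
        import hashlib

        def fn(spacer: str) -> float:
            h = hashlib.sha256(f"{seed}:{spacer}".encode()).digest()
            return int.from_bytes(h[:8], "little") / 2**64

        return cls(fn, name=name)
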