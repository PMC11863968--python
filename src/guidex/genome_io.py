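"""Genome, annotation and interval I/O.

Defines the coordinate and alphabet conventions used by every other module:

* all internal coordinates are 0-based half-open; GTF/GFF (1-based inclusive)
  and SAM (1-based) are converted at the parsing/emission boundary only;
* sequences are uppercased on load and restricted to the alphabet
  ``{A, C, G, T, N}`` — any other IUPAC ambiguity code collapses to ``N``;
* in the concatenated genome text, sequences are joined by a separator
  symbol that can never match a pattern character, so searches cannot span
  sequence boundaries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")
# IUPAC one-letter codes other than ACGT collapse to N on load.
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVUN"})


class GenomeError(ValueError):
    """Malformed genome or annotation input."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map non-ACGT IUPAC codes to N; reject anything else."""
    s = seq.upper().translate(_IUPAC_TO_N)
    bad = set(s) - VALID_BASES
    if bad:
        raise GenomeError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise GenomeError(f"cannot complement characters: {sorted(bad)}")
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named nucleotide sequences plus the layout of their concatenation.

    ``offsets[name]`` is the 0-based start of that sequence in the
    concatenated text, where consecutive sequences are separated by one
    separator symbol (so the concatenated length is ``sum(lengths) +
    n_sequences - 1`` before the final terminator an index appends).
    """

    sequences: dict[str, str]
    lengths: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = {name: len(s) for name, s in self.sequences.items()}
        self.offsets = {}
        pos = 0
        for name, length in self.lengths.items():
            self.offsets[name] = pos
            pos += length + 1  # +1 for the inter-sequence separator / terminator

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def total_length(self) -> int:
        return sum(self.lengths.values())

    def concatenated(self, separator: str = "#") -> str:
        """The genome text with one separator between sequences (no terminator)."""
        return separator.join(self.sequences.values())

    def global_to_local(self, gpos: int) -> tuple[str, int]:
        """Map a position in the concatenated text to (sequence name, local pos)."""
        for name in reversed(self.offsets):
            off = self.offsets[name]
            if gpos >= off:
                local = gpos - off
                if local >= self.lengths[name]:
                    raise GenomeError(f"global position {gpos} falls in a separator")
                return name, local
        raise GenomeError(f"global position {gpos} out of range")

    def local_to_global(self, name: str, pos: int) -> int:
        return self.offsets[name] + pos


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    sequence: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GenomeError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence}"
            )
        if self.strand not in "+-":
            raise GenomeError(f"invalid strand {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Annotation:
    """Gene models: gene/exon/CDS intervals keyed by gene id."""

    genes: dict[str, GenomicInterval]
    exons: dict[str, list[GenomicInterval]]
    cds: dict[str, list[GenomicInterval]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def all_cds(self) -> Iterator[tuple[str, GenomicInterval]]:
        for gid, ivs in self.cds.items():
            for iv in ivs:
                yield gid, iv

    def all_exons(self) -> Iterator[tuple[str, GenomicInterval]]:
        for gid, ivs in self.exons.items():
            for iv in ivs:
                yield gid, iv


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str) -> Genome:
    """Load a (possibly gzipped) FASTA into a :class:`Genome`.

    Lowercase (soft-masked) residues are uppercased and treated as
    targetable; ambiguity codes other than ACGT become N. Duplicate record
    names and empty files are hard errors.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise GenomeError(f"duplicate FASTA record name: {record.id}")
            sequences[record.id] = normalize_sequence(str(record.seq))
    if not sequences:
        raise GenomeError(f"no FASTA records found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Parse BED3/BED6. BED is already 0-based half-open; kept as-is.

    Overlapping lines are retained without merging.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise GenomeError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            intervals.append(GenomicInterval(chrom, start, end, strand, label))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.sequence}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


def read_annotation(path: str, fmt: str | None = None) -> Annotation:
    """Parse gene/exon/CDS features from GTF or GFF3 into 0-based half-open
    intervals. ``fmt`` is inferred from the extension when omitted.

    Every exon/CDS must resolve a gene id present among the gene features.
    """
    import gffutils

    if fmt is None:
        low = str(path).lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")) else "gtf"
    if fmt not in ("gtf", "gff3"):
        raise GenomeError(f"unknown annotation format: {fmt}")

    _validate_feature_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}

    def _gene_id(feature) -> str:
        for key in ("gene_id", "Parent", "ID", "gene"):
            if key in feature.attributes:
                val = feature.attributes[key][0]
                # GFF3 Parent may point at a transcript: strip to the gene id
                # via the db if needed (handled by the caller's resolution loop).
                return val
        raise GenomeError(
            f"feature at {feature.seqid}:{feature.start}-{feature.end} has no gene id"
        )

    for f in db.features_of_type("gene"):
        gid = _gene_id(f)
        genes[gid] = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand or "+", gid)

    def _resolve_gene(f) -> str:
        gid = _gene_id(f)
        if gid in genes:
            return gid
        # GFF3: walk Parent chain (exon -> mRNA -> gene)
        seen = set()
        cur = gid
        while cur not in genes:
            if cur in seen:
                break
            seen.add(cur)
            try:
                parent = db[cur]
            except Exception:
                break
            pids = parent.attributes.get("Parent", [])
            gids = parent.attributes.get("gene_id", [])
            nxt = (gids or pids or [None])[0]
            if nxt is None:
                break
            cur = nxt
        if cur in genes:
            return cur
        raise GenomeError(f"cannot resolve gene id for feature {f.id} ({gid})")

    for kind, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(kind):
            gid = _resolve_gene(f)
            store.setdefault(gid, []).append(
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand or "+", gid)
            )
    return Annotation(genes=genes, exons=exons, cds=cds)


def _validate_feature_lines(path: str) -> None:
    """Cheap pre-pass so malformed lines are reported with their number."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GenomeError(f"{path}:{lineno}: invalid 1-based coordinates")


def write_gtf(annotation: Annotation, path: str, source: str = "guidex") -> None:
    """Emit the annotation as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gid, gene in annotation.genes.items():
            rows = [("gene", gene)]
            rows += [("exon", iv) for iv in annotation.exons.get(gid, [])]
            rows += [("CDS", iv) for iv in annotation.cds.get(gid, [])]
            for kind, iv in rows:
                attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
                fh.write(
                    f"{iv.sequence}\t{source}\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
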