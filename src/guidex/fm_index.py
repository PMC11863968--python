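"""FM-index over the concatenated genome.

The index is a Burrows-Wheeler transform of ``seq1 # seq2 # ... # seqK $``
over the 6-symbol alphabet ``{$, #, A, C, G, T}`` (codes 0..5). ``N`` bases
are replaced by the separator code at index time, so no pattern can match
through an N run and no match can span a sequence boundary. Backward search
over suffix-array intervals is the substrate for the reverse-prefix trie
traversal in :mod:`guidex.offtarget_search`: each ``SAInterval`` is one
simulated trie node.

Only the forward text is indexed; minus-strand search queries the reverse
complement of the pattern and maps coordinates back.

The suffix array is built by numpy prefix doubling (O(n log^2 n)), which is
worst-case safe on repetitive input at the genome sizes this package
targets (up to a few megabases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GenomeError, reverse_complement

TERMINATOR = 0
SEPARATOR = 1
BASE_CODE = {"A": 2, "C": 3, "G": 4, "T": 5}
CODE_BASE = {v: k for k, v in BASE_CODE.items()}
ALPHABET_SIZE = 6

_MAGIC = b"GDXFMI1\n"
_FORMAT_VERSION = 1

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
_ENCODE_TABLE[ord("N")] = SEPARATOR
_ENCODE_TABLE[ord("#")] = SEPARATOR
_ENCODE_TABLE[ord("$")] = TERMINATOR


class IndexError_(ValueError):
    """FM-index construction or serialization failure."""


def encode_text(text: str) -> np.ndarray:
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[arr]
    if (codes < 0).any():
        bad = sorted({chr(c) for c in arr[codes < 0]})
        raise IndexError_(f"cannot encode characters {bad}")
    return codes.astype(np.uint8)


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy argsort based)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        # sort by (rank[i], rank[i+k]) using lexsort
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        tmp[sa[0]] = 0
        prev, cur = sa[:-1], sa[1:]
        newgroup = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(newgroup)
        rank, tmp = tmp, rank
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa.astype(np.int64)


@dataclass(frozen=True)
class SAInterval:
    """Half-open interval of the suffix array; a simulated trie node."""

    low: int
    high: int
    depth: int = 0

    @property
    def width(self) -> int:
        return self.high - self.low

    @property
    def empty(self) -> bool:
        return self.high <= self.low


class FMIndex:
    """Searchable BWT index with occurrence checkpoints and SA samples."""

    def __init__(
        self,
        bwt: np.ndarray,
        occ: np.ndarray,
        counts: np.ndarray,
        sa_marked: np.ndarray,
        sa_sample_values: np.ndarray,
        sa_sample_rate: int,
        seq_names: list[str],
        seq_lengths: list[int],
    ):
        self.bwt = bwt
        self.occ = occ  # (n+1, 6) cumulative symbol counts over the BWT
        self.C = counts  # C[c] = number of text symbols smaller than c
        self.sa_marked = sa_marked
        # rank of each marked row among marked rows, for O(1) sample lookup
        self._marked_rank = np.cumsum(sa_marked) - 1
        self.sa_sample_values = sa_sample_values
        self.sa_sample_rate = int(sa_sample_rate)
        self.seq_names = list(seq_names)
        self.seq_lengths = list(seq_lengths)
        self.text_length = len(bwt)
        self.seq_offsets = []
        pos = 0
        for length in self.seq_lengths:
            self.seq_offsets.append(pos)
            pos += length + 1

    # -- construction -----------------------------------------------------

    @classmethod
    def build(cls, genome: Genome, sa_sample_rate: int = 16) -> "FMIndex":
        if not genome.sequences:
            raise IndexError_("cannot index an empty genome")
        if sa_sample_rate < 1:
            raise IndexError_("sa_sample_rate must be >= 1")
        text = genome.concatenated("#") + "$"
        codes = encode_text(text)
        sa = suffix_array(codes)
        n = len(codes)
        prev = sa - 1
        prev[prev < 0] = n - 1
        bwt = codes[prev]
        occ = np.zeros((n + 1, ALPHABET_SIZE), dtype=np.int64)
        onehot = np.zeros((n, ALPHABET_SIZE), dtype=np.int64)
        onehot[np.arange(n), bwt] = 1
        np.cumsum(onehot, axis=0, out=occ[1:])
        totals = occ[n]
        counts = np.zeros(ALPHABET_SIZE, dtype=np.int64)
        counts[1:] = np.cumsum(totals)[:-1]
        marked = (sa % sa_sample_rate) == 0
        samples = sa[marked]
        return cls(
            bwt=bwt.astype(np.uint8),
            occ=occ,
            counts=counts,
            sa_marked=marked,
            sa_sample_values=samples.astype(np.int64),
            sa_sample_rate=sa_sample_rate,
            seq_names=genome.names,
            seq_lengths=[genome.lengths[s] for s in genome.names],
        )

    # -- backward search --------------------------------------------------

    def root(self) -> SAInterval:
        return SAInterval(0, self.text_length, 0)

    def extend(self, interval: SAInterval, symbol: str | int) -> SAInterval:
        """Backward-search extension: prepend ``symbol`` to the pattern."""
        if interval.empty:
            return SAInterval(interval.low, interval.low, interval.depth + 1)
        c = BASE_CODE[symbol] if isinstance(symbol, str) else int(symbol)
        lo = self.C[c] + self.occ[interval.low, c]
        hi = self.C[c] + self.occ[interval.high, c]
        return SAInterval(int(lo), int(hi), interval.depth + 1)

    def interval_for(self, pattern: str) -> SAInterval:
        iv = self.root()
        for ch in reversed(pattern):
            if ch not in BASE_CODE:
                return SAInterval(0, 0, len(pattern))
            iv = self.extend(iv, ch)
            if iv.empty:
                return iv
        return iv

    def count(self, pattern: str) -> int:
        """Occurrences of ``pattern`` in the forward concatenated text."""
        return self.interval_for(pattern).width

    def count_both_strands(self, pattern: str) -> int:
        return self.count(pattern) + self.count(reverse_complement(pattern))

    # -- locate -----------------------------------------------------------

    def _lf(self, row: int) -> int:
        c = self.bwt[row]
        return int(self.C[c] + self.occ[row, c])

    def text_position(self, row: int) -> int:
        """Text position of the suffix at SA row, via LF-walk to a sample."""
        steps = 0
        while not self.sa_marked[row]:
            row = self._lf(row)
            steps += 1
        return int(self.sa_sample_values[self._marked_rank[row]]) + steps

    def global_to_local(self, gpos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(np.asarray(self.seq_offsets), gpos, side="right")) - 1
        local = gpos - self.seq_offsets[idx]
        if local >= self.seq_lengths[idx]:
            raise IndexError_(f"position {gpos} maps into a separator")
        return self.seq_names[idx], local

    def locate(self, interval: SAInterval) -> list[tuple[str, int]]:
        """(sequence, 0-based position) for every suffix in the interval,
        sorted by (sequence order, position)."""
        out = []
        for row in range(interval.low, interval.high):
            gpos = self.text_position(row)
            name, local = self.global_to_local(gpos)
            out.append((self.seq_names.index(name), name, local))
        out.sort()
        return [(name, pos) for _, name, pos in out]

    # -- serialization ----------------------------------------------------

    def save(self, path: str) -> None:
        """Write a single-file binary index: magic, versioned JSON header,
        then length-prefixed raw arrays (deterministic byte layout)."""
        meta = {
            "format_version": _FORMAT_VERSION,
            "sa_sample_rate": self.sa_sample_rate,
            "seq_names": self.seq_names,
            "seq_lengths": self.seq_lengths,
            "text_length": self.text_length,
        }
        blobs = [
            self.bwt.astype(np.uint8).tobytes(),
            np.packbits(self.sa_marked).tobytes(),
            self.sa_sample_values.astype("<i8").tobytes(),
        ]
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            meta_bytes = json.dumps(meta, sort_keys=True).encode()
            fh.write(len(meta_bytes).to_bytes(8, "little"))
            fh.write(meta_bytes)
            for blob in blobs:
                fh.write(len(blob).to_bytes(8, "little"))
                fh.write(blob)

    @classmethod
    def load(cls, path: str) -> "FMIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise IndexError_(f"{path}: not a guidex index (bad magic)")
            meta_len = int.from_bytes(fh.read(8), "little")
            try:
                meta = json.loads(fh.read(meta_len).decode())
            except Exception as exc:
                raise IndexError_(f"{path}: corrupted index header") from exc
            if meta.get("format_version") != _FORMAT_VERSION:
                raise IndexError_(
                    f"{path}: index format version {meta.get('format_version')} "
                    f"!= supported {_FORMAT_VERSION}"
                )

            def _blob() -> bytes:
                raw = fh.read(8)
                if len(raw) != 8:
                    raise IndexError_(f"{path}: truncated index payload")
                size = int.from_bytes(raw, "little")
                data = fh.read(size)
                if len(data) != size:
                    raise IndexError_(f"{path}: truncated index payload")
                return data

            n = int(meta["text_length"])
            bwt = np.frombuffer(_blob(), dtype=np.uint8)
            marked_packed = np.frombuffer(_blob(), dtype=np.uint8)
            samples = np.frombuffer(_blob(), dtype="<i8").astype(np.int64)
        if len(bwt) != n or (bwt >= ALPHABET_SIZE).any():
            raise IndexError_(f"{path}: corrupted index (bad BWT)")
        occ = np.zeros((n + 1, ALPHABET_SIZE), dtype=np.int64)
        onehot = np.zeros((n, ALPHABET_SIZE), dtype=np.int64)
        onehot[np.arange(n), bwt] = 1
        np.cumsum(onehot, axis=0, out=occ[1:])
        totals = occ[n]
        counts = np.zeros(ALPHABET_SIZE, dtype=np.int64)
        counts[1:] = np.cumsum(totals)[:-1]
        marked = np.unpackbits(marked_packed)[:n].astype(bool)
        return cls(
            bwt=bwt,
            occ=occ,
            counts=counts,
            sa_marked=marked,
            sa_sample_values=samples,
            sa_sample_rate=int(meta["sa_sample_rate"]),
            seq_names=list(meta["seq_names"]),
            seq_lengths=[int(x) for x in meta["seq_lengths"]],
        )


def build_index(genome: Genome, sa_sample_rate: int = 16) -> FMIndex:
    return FMIndex.build(genome, sa_sample_rate=sa_sample_rate)


def save_index(index: FMIndex, path: str) -> None:
    index.save(path)


def load_index(path: str) -> FMIndex:
    return FMIndex.load(path)
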