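"""Read ingestion and the sentinel-delimited read text.

The FM-index in this package is built over the *reads*, not a reference:
all read sequences are stripped of qualities, uppercased, and concatenated
into a single text with a sentinel ``$`` after every read.  Because query
k-mers never contain the sentinel, a match can never span two reads.

The :class:`ReadStore` keeps the bookkeeping needed to translate a text
position back into ``(read ordinal, offset, is_rc_copy)``: per-segment
offsets, the owning read ordinal of each segment (a segment is either a
read or, when ``rc_included``, its appended reverse-complement copy), and
pairing metadata.  Mates of a pair are interleaved so that
``pair_id = ordinal // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pysam

SENTINEL = "$"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, record_name: str = "<record>") -> str:
    """Uppercase, map U->T, and validate against {A,C,G,T,N}.

    Raises ``ValueError`` naming the offending record otherwise.
    """
    up = seq.upper().replace("U", "T")
    if not up:
        raise ValueError(f"empty sequence in record {record_name!r}")
    bad = set(up) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_name!r} contains invalid symbols: "
            f"{''.join(sorted(bad))!r}"
        )
    return up


@dataclass(frozen=True)
class ReadMeta:
    """Per-read metadata: global-dense ordinal, length, mate slot, source."""

    ordinal: int
    length: int
    mate: int = 0  # 0 for single-end or R1, 1 for R2
    source_file: str = ""


@dataclass
class StoreManifest:
    """Everything the search stage needs to map text positions to reads.

    Serialized alongside (and inside) each index chunk so that collation
    does not need the read text itself.
    """

    chunk_id: int
    global_ordinal_offset: int
    paired: bool
    rc_included: bool
    n_reads: int
    seg_lengths: np.ndarray       # length of each stored segment
    seg_ordinal: np.ndarray       # local read ordinal owning each segment
    seg_is_rc: np.ndarray         # True for appended reverse-complement copies
    source_files: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.seg_lengths = np.asarray(self.seg_lengths, dtype=np.int64)
        self.seg_ordinal = np.asarray(self.seg_ordinal, dtype=np.int64)
        self.seg_is_rc = np.asarray(self.seg_is_rc, dtype=bool)

    @property
    def offsets(self) -> np.ndarray:
        """Start position of each segment in the sentinel-delimited text."""
        starts = np.zeros(len(self.seg_lengths), dtype=np.int64)
        if len(self.seg_lengths) > 1:
            np.cumsum(self.seg_lengths[:-1] + 1, out=starts[1:])
        return starts

    @property
    def text_length(self) -> int:
        return int(np.sum(self.seg_lengths + 1))

    def map_positions(self, positions: np.ndarray):
        """Vectorized text position -> (global ordinal, offset, is_rc).

        Raises ``RuntimeError`` if any position falls on a sentinel: the
        search layer can never legitimately produce one.
        """
        positions = np.asarray(positions, dtype=np.int64)
        offs = self.offsets
        seg = np.searchsorted(offs, positions, side="right") - 1
        in_seg = positions - offs[seg]
        if np.any(in_seg >= self.seg_lengths[seg]):
            bad = positions[in_seg >= self.seg_lengths[seg]][0]
            raise RuntimeError(
                f"text position {bad} is a sentinel: matches must lie inside reads"
            )
        ordinals = self.seg_ordinal[seg] + self.global_ordinal_offset
        return ordinals, in_seg, self.seg_is_rc[seg]

    def to_dict(self) -> dict:
        return {
            "chunk_id": self.chunk_id,
            "global_ordinal_offset": self.global_ordinal_offset,
            "paired": self.paired,
            "rc_included": self.rc_included,
            "n_reads": self.n_reads,
            "seg_lengths": self.seg_lengths.tolist(),
            "seg_ordinal": self.seg_ordinal.tolist(),
            "seg_is_rc": [bool(x) for x in self.seg_is_rc],
            "source_files": list(self.source_files),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StoreManifest":
        return cls(
            chunk_id=int(d["chunk_id"]),
            global_ordinal_offset=int(d["global_ordinal_offset"]),
            paired=bool(d["paired"]),
            rc_included=bool(d["rc_included"]),
            n_reads=int(d["n_reads"]),
            seg_lengths=np.asarray(d["seg_lengths"], dtype=np.int64),
            seg_ordinal=np.asarray(d["seg_ordinal"], dtype=np.int64),
            seg_is_rc=np.asarray(d["seg_is_rc"], dtype=bool),
            source_files=tuple(d.get("source_files", ())),
        )


@dataclass
class ReadStore:
    """A read set as a single sentinel-delimited text plus bookkeeping."""

    text: str
    metas: list[ReadMeta]
    paired: bool = False
    rc_included: bool = False
    chunk_id: int = 0
    global_ordinal_offset: int = 0
    source_files: tuple[str, ...] = ()
    # per-segment arrays (a segment = read or its RC copy)
    seg_lengths: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    seg_ordinal: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    seg_is_rc: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def n_reads(self) -> int:
        return len(self.metas)

    @property
    def n_segments(self) -> int:
        return len(self.seg_lengths)

    @property
    def offsets(self) -> np.ndarray:
        return self.manifest().offsets

    def manifest(self) -> StoreManifest:
        return StoreManifest(
            chunk_id=self.chunk_id,
            global_ordinal_offset=self.global_ordinal_offset,
            paired=self.paired,
            rc_included=self.rc_included,
            n_reads=self.n_reads,
            seg_lengths=self.seg_lengths,
            seg_ordinal=self.seg_ordinal,
            seg_is_rc=self.seg_is_rc,
            source_files=self.source_files,
        )

    def read_sequence(self, local_ordinal: int) -> str:
        """The forward sequence of a read, recovered from the text."""
        offs = self.offsets
        fwd = np.flatnonzero((self.seg_ordinal == local_ordinal) & ~self.seg_is_rc)
        if fwd.size == 0:
            raise IndexError(f"no read with local ordinal {local_ordinal}")
        i = int(fwd[0])
        start = int(offs[i])
        return self.text[start : start + int(self.seg_lengths[i])]

    def iter_reads(self) -> Iterator[tuple[int, str]]:
        """Yield (global ordinal, forward sequence) in ordinal order."""
        offs = self.offsets
        for i in range(self.n_segments):
            if not self.seg_is_rc[i]:
                start = int(offs[i])
                seq = self.text[start : start + int(self.seg_lengths[i])]
                yield int(self.seg_ordinal[i]) + self.global_ordinal_offset, seq


def _assemble(
    sequences: Sequence[str],
    metas: list[ReadMeta],
    *,
    paired: bool,
    include_rc: bool,
    chunk_id: int = 0,
    global_ordinal_offset: int = 0,
    source_files: tuple[str, ...] = (),
) -> ReadStore:
    parts: list[str] = []
    seg_lengths: list[int] = []
    seg_ordinal: list[int] = []
    seg_is_rc: list[bool] = []
    for meta, seq in zip(metas, sequences):
        parts.append(seq)
        parts.append(SENTINEL)
        seg_lengths.append(len(seq))
        seg_ordinal.append(meta.ordinal)
        seg_is_rc.append(False)
        if include_rc:
            rc = reverse_complement(seq)
            parts.append(rc)
            parts.append(SENTINEL)
            seg_lengths.append(len(rc))
            seg_ordinal.append(meta.ordinal)
            seg_is_rc.append(True)
    return ReadStore(
        text="".join(parts),
        metas=metas,
        paired=paired,
        rc_included=include_rc,
        chunk_id=chunk_id,
        global_ordinal_offset=global_ordinal_offset,
        source_files=source_files,
        seg_lengths=np.asarray(seg_lengths, dtype=np.int64),
        seg_ordinal=np.asarray(seg_ordinal, dtype=np.int64),
        seg_is_rc=np.asarray(seg_is_rc, dtype=bool),
    )


def store_from_sequences(
    sequences: Sequence[str],
    *,
    paired: bool = False,
    include_rc: bool = False,
) -> ReadStore:
    """Build a store directly from in-memory sequences (tests, simulation)."""
    if not sequences:
        raise ValueError("no reads given")
    if paired and len(sequences) % 2:
        raise ValueError("paired store requires an even number of reads")
    seqs = [normalize_sequence(s, f"read{i}") for i, s in enumerate(sequences)]
    metas = [
        ReadMeta(ordinal=i, length=len(s), mate=(i % 2 if paired else 0))
        for i, s in enumerate(seqs)
    ]
    return _assemble(seqs, metas, paired=paired, include_rc=include_rc)


def _parse_file(path: str) -> list[tuple[str, str]]:
    """Read (name, normalized sequence) records from FASTA/FASTQ, plain or gz."""
    out: list[tuple[str, str]] = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out.append((rec.name, normalize_sequence(rec.sequence or "", rec.name)))
    return out


def load_reads(
    paths: Sequence[str],
    *,
    paired: bool = False,
    interleaved: bool = False,
    include_rc: bool = False,
) -> ReadStore:
    """Load FASTQ/FASTA files into a :class:`ReadStore`.

    Qualities and headers are discarded; sequences are uppercased with
    ``U -> T``.  With ``paired`` and two files, R1/R2 records are
    interleaved (R1_i at ordinal ``2i``, R2_i at ``2i+1``); with
    ``paired`` and ``interleaved``, one file already alternating mates is
    accepted.  ``include_rc`` appends each read's reverse complement
    immediately after it, sharing the forward read's ordinal.
    """
    paths = [str(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    sequences: list[str]
    mates: list[int]
    sources: list[str]
    if paired and not interleaved:
        if len(paths) != 2:
            raise ValueError("paired mode requires exactly two files (or --interleaved)")
        r1 = _parse_file(paths[0])
        r2 = _parse_file(paths[1])
        if len(r1) != len(r2):
            raise ValueError(
                f"mismatched pair files: {paths[0]} has {len(r1)} records, "
                f"{paths[1]} has {len(r2)}"
            )
        sequences, mates, sources = [], [], []
        for (_, s1), (_, s2) in zip(r1, r2):
            sequences.extend((s1, s2))
            mates.extend((0, 1))
            sources.extend((paths[0], paths[1]))
    else:
        records: list[tuple[str, str, str]] = []
        for p in paths:
            records.extend((name, seq, p) for name, seq in _parse_file(p))
        if paired:  # interleaved single file(s)
            if len(records) % 2:
                raise ValueError("interleaved paired input has an odd record count")
            mates = [i % 2 for i in range(len(records))]
        else:
            mates = [0] * len(records)
        sequences = [seq for _, seq, _ in records]
        sources = [src for _, _, src in records]
    if not sequences:
        raise ValueError("input files contain no reads")
    metas = [
        ReadMeta(ordinal=i, length=len(s), mate=m, source_file=src)
        for i, (s, m, src) in enumerate(zip(sequences, mates, sources))
    ]
    return _assemble(
        sequences,
        metas,
        paired=paired,
        include_rc=include_rc,
        source_files=tuple(dict.fromkeys(paths)),
    )


def split_chunks(store: ReadStore, n_chunks: int) -> list[ReadStore]:
    """Partition a store contiguously by ordinal into independent chunks.

    Paired mates are never split across chunks; each chunk records its
    ``global_ordinal_offset`` so global read IDs stay recoverable.
    """
    unit = 2 if store.paired else 1
    n_units = store.n_reads // unit
    if not 1 <= n_chunks <= max(n_units, 0):
        raise ValueError(
            f"n_chunks={n_chunks} outside [1, {n_units}] for this store"
        )
    unit_splits = np.array_split(np.arange(n_units), n_chunks)
    seqs_by_ordinal = {loc: seq for loc, seq in
                       ((m.ordinal, store.read_sequence(m.ordinal)) for m in store.metas)}
    chunks: list[ReadStore] = []
    for cid, units in enumerate(unit_splits):
        lo = int(units[0]) * unit
        hi = (int(units[-1]) + 1) * unit
        metas = [
            ReadMeta(ordinal=i - lo, length=store.metas[i].length,
                     mate=store.metas[i].mate, source_file=store.metas[i].source_file)
            for i in range(lo, hi)
        ]
        seqs = [seqs_by_ordinal[i] for i in range(lo, hi)]
        chunk = _assemble(
            seqs,
            metas,
            paired=store.paired,
            include_rc=store.rc_included,
            chunk_id=cid,
            global_ordinal_offset=store.global_ordinal_offset + lo,
            source_files=store.source_files,
        )
        chunks.append(chunk)
    return chunks


def position_to_read(store: ReadStore, text_position: int) -> tuple[int, int, bool]:
    """Map a text position to (global read ordinal, offset in read, is_rc_copy).

    Sentinel positions raise: a search hit can never touch a sentinel, so
    one arriving here signals an internal bug.
    """
    if not 0 <= text_position < len(store.text):
        raise IndexError(f"position {text_position} outside text")
    ordinals, in_seg, is_rc = store.manifest().map_positions(
        np.asarray([text_position])
    )
    return int(ordinals[0]), int(in_seg[0]), bool(is_rc[0])


def read_to_pair(store: ReadStore, ordinal: int) -> int:
    """Pair id of a global ordinal: ``ordinal // 2`` when paired, else identity."""
    return ordinal // 2 if store.paired else ordinal
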