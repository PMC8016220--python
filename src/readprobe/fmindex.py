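"""FM-index over the sentinel-delimited read text.

Construction pipeline: suffix array -> BWT -> per-symbol occurrence table
-> sampled suffix array.  ``backward_search`` answers exact pattern counts
in O(|pattern|) table lookups; ``locate`` resolves the suffix-array
interval to text positions by LF-walking to the nearest sampled slot.

Two internal conventions worth knowing:

* The suffix order is the order of the *rotations* of the text, with ties
  broken by position.  The text terminator is encoded as a symbol strictly
  smaller than the read separators, which makes every rotation distinct,
  so the LF mapping is exact at every row — locate walks may cross read
  boundaries without special cases.  Externally both separator codes
  render as ``$`` and all black-box behaviour (counts, positions) matches
  the plain suffix-array view, because query patterns never contain a
  sentinel.
* The occurrence (rank) structure is a dense per-symbol cumulative table:
  ``occ[p, c]`` = number of ``c`` among ``bwt[:p]``.  That is an O(1),
  fully vectorizable rank query at ~28 bytes/base — a deliberate
  memory-for-speed trade at the scales this package targets.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .readstore import ReadStore, StoreManifest, split_chunks

# symbol codes: 0 = text terminator, 1 = read separator, then the bases.
TERM = 0
SEP = 1
ALPHABET = "$$ACGNT"  # code -> rendered character (both sentinels print as $)
N_SYMBOLS = 7

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate("ACGNT"):
    _ENCODE[ord(_ch)] = 2 + _i
_ENCODE[ord("$")] = SEP

MAGIC = b"RPIX"
FORMAT_VERSION = 1
DEFAULT_SAMPLE_RATE = 16


class IndexFormatError(ValueError):
    """Raised when an index file is truncated, corrupt, or wrong-version."""


@dataclass(frozen=True)
class Overflow:
    """Marker returned by locate when a pattern occurs more than max_hits times.

    Carries the exact total occurrence count so that downstream logic can
    still apply a *global* max-occurrence rule across chunks.
    """

    total: int


def encode_text(text: str) -> np.ndarray:
    """Map a sentinel-delimited read text to symbol codes.

    The final character must be a sentinel; it receives the distinct
    terminator code.
    """
    if not text:
        raise ValueError("empty text")
    if text[-1] != "$":
        raise ValueError("text must end with a sentinel")
    raw = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if np.any(codes < 0):
        bad = chr(int(raw[np.argmax(codes < 0)]))
        raise ValueError(f"text contains a symbol outside the alphabet: {bad!r}")
    codes = codes.astype(np.int64)
    codes[-1] = TERM
    return codes


def encode_pattern(pattern: str) -> np.ndarray:
    """Symbol codes for a query pattern; -1 marks out-of-alphabet symbols.

    Sentinels are not legal in patterns.
    """
    raw = np.frombuffer(pattern.upper().encode("ascii", errors="replace"), np.uint8)
    codes = _ENCODE[raw].astype(np.int64)
    codes[raw == ord("$")] = -1
    return codes


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Sort all rotations of ``codes`` by prefix doubling (ties by position).

    With the distinct terminator every rotation is unique, so this equals
    the multi-string suffix order with sentinels ranked by position.
    O(n log^2 n) via numpy lexsort; the loop exits as soon as ranks are
    fully distinct, which for read-like texts happens after ~log2(read
    length) rounds.
    """
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    idx = np.arange(n)
    if n == 1:
        return idx
    k = 1
    while True:
        key2 = np.roll(rank, -k)
        order = np.lexsort((idx, key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1 or k >= n:
            return order
        k *= 2


def build_suffix_array(text: Union[str, np.ndarray]) -> np.ndarray:
    """Suffix array of a sentinel-terminated text (string or code array)."""
    codes = encode_text(text) if isinstance(text, str) else np.asarray(text)
    return suffix_array(codes)


@dataclass
class FMIndexBundle:
    """One chunk's FM-index: BWT + counts + rank table + sampled SA."""

    bwt_codes: np.ndarray          # uint8, length n
    counts_before: np.ndarray      # int64, len N_SYMBOLS+1; counts_before[c] = #codes < c
    occ: np.ndarray                # int32 (n+1, N_SYMBOLS); occ[p, c] = #c in bwt[:p]
    row_sa: np.ndarray             # int64, sampled SA by row; -1 where unsampled
    sample_rate: int
    text_length: int
    chunk_id: int
    manifest: StoreManifest

    # -- basic views ---------------------------------------------------

    @property
    def bwt(self) -> str:
        """The BWT as a string (both sentinel codes rendered as ``$``)."""
        lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
        return lut[self.bwt_codes].tobytes().decode("ascii")

    def symbol_counts(self) -> dict[str, int]:
        totals = np.diff(self.counts_before)
        out: dict[str, int] = {}
        for c in range(N_SYMBOLS):
            ch = ALPHABET[c]
            out[ch] = out.get(ch, 0) + int(totals[c])
        return out

    # -- rank / LF ------------------------------------------------------

    def occ_query(self, symbol: int, prefix_length: int) -> int:
        """Number of occurrences of ``symbol`` in ``bwt[:prefix_length]``."""
        return int(self.occ[prefix_length, symbol])

    def lf(self, rows: np.ndarray) -> np.ndarray:
        c = self.bwt_codes[rows].astype(np.int64)
        return self.counts_before[c] + self.occ[rows, c]

    # -- search ---------------------------------------------------------

    def backward_search(self, pattern: str) -> tuple[int, int]:
        """Half-open SA interval [lo, hi) of suffixes prefixed by pattern."""
        if not pattern:
            raise ValueError("empty pattern")
        if "$" in pattern:
            raise ValueError("patterns may not contain the sentinel symbol")
        codes = encode_pattern(pattern)
        if np.any(codes < 0):
            return (0, 0)
        lo, hi = 0, self.text_length
        C = self.counts_before
        for c in codes[::-1]:
            lo = int(C[c] + self.occ[lo, c])
            hi = int(C[c] + self.occ[hi, c])
            if lo >= hi:
                return (0, 0)
        return (lo, hi)

    def backward_search_batch(self, pattern_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized backward search over an (m, k) matrix of pattern codes.

        Rows containing code -1 get an empty interval.  All patterns must
        share one length; group by length upstream.
        """
        pats = np.asarray(pattern_codes, dtype=np.int64)
        m, k = pats.shape
        valid = np.all(pats >= 0, axis=1)
        safe = np.where(pats >= 0, pats, 0)
        lo = np.zeros(m, dtype=np.int64)
        hi = np.full(m, self.text_length, dtype=np.int64)
        C = self.counts_before
        for j in range(k - 1, -1, -1):
            c = safe[:, j]
            lo = C[c] + self.occ[lo, c]
            hi = C[c] + self.occ[hi, c]
        empty = (hi <= lo) | ~valid
        lo[empty] = 0
        hi[empty] = 0
        return lo, hi

    def count(self, pattern: str) -> int:
        lo, hi = self.backward_search(pattern)
        return hi - lo

    def locate_rows(self, rows: np.ndarray) -> np.ndarray:
        """Text positions of SA rows via LF-walk to the nearest sampled slot."""
        rows = np.asarray(rows, dtype=np.int64)
        res = np.full(rows.shape, -1, dtype=np.int64)
        cur = rows.copy()
        pending = np.arange(len(rows))
        steps = 0
        while pending.size:
            v = self.row_sa[cur[pending]]
            done = v >= 0
            res[pending[done]] = v[done] + steps
            pending = pending[~done]
            if pending.size:
                cur[pending] = self.lf(cur[pending])
                steps += 1
        return res

    def locate(self, pattern: str, max_hits: int) -> Union[list[int], Overflow]:
        """Ascending text positions of a pattern, or Overflow(total) past max_hits."""
        if max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        lo, hi = self.backward_search(pattern)
        size = hi - lo
        if size == 0:
            return []
        if size > max_hits:
            return Overflow(total=size)
        pos = self.locate_rows(np.arange(lo, hi))
        return sorted(int(p) for p in pos)

    # -- reconstruction (used by tests as an identity check) -------------

    def reconstruct_text(self) -> str:
        """Invert the BWT back to the original text via repeated LF steps."""
        n = self.text_length
        out = np.empty(n, dtype=np.uint8)
        lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
        i = 0  # row 0 is the rotation starting at the terminator (position n-1)
        for t in range(1, n):
            c = int(self.bwt_codes[i])
            out[n - 1 - t] = lut[c]
            i = int(self.counts_before[c] + self.occ[i, c])
        out[n - 1] = ord("$")
        return out.tobytes().decode("ascii")

    # -- serialization ----------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Write the bundle to a versioned binary file (deterministic bytes)."""
        slots = np.flatnonzero(self.row_sa >= 0).astype(np.int64)
        vals = self.row_sa[slots]
        header = {
            "format": "readprobe-fm-index",
            "version": FORMAT_VERSION,
            "alphabet": ALPHABET,
            "n": self.text_length,
            "sample_rate": self.sample_rate,
            "chunk_id": self.chunk_id,
            "n_samples": int(slots.size),
            "manifest": self.manifest.to_dict(),
        }
        hjson = json.dumps(header, sort_keys=True).encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(struct.pack("<I", FORMAT_VERSION))
            fh.write(struct.pack("<Q", len(hjson)))
            fh.write(hjson)
            fh.write(self.bwt_codes.astype(np.uint8).tobytes())
            fh.write(slots.tobytes())
            fh.write(vals.tobytes())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FMIndexBundle":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != MAGIC:
                raise IndexFormatError(f"{path}: not a readprobe index (bad magic)")
            (version,) = struct.unpack("<I", fh.read(4))
            if version != FORMAT_VERSION:
                raise IndexFormatError(
                    f"{path}: unsupported index version {version}"
                )
            (hlen,) = struct.unpack("<Q", fh.read(8))
            header = json.loads(fh.read(hlen).decode("utf-8"))
            n = int(header["n"])
            n_samples = int(header["n_samples"])
            payload = fh.read()
        expected = n + 16 * n_samples
        if len(payload) != expected:
            raise IndexFormatError(
                f"{path}: truncated index payload ({len(payload)} != {expected} bytes)"
            )
        bwt_codes = np.frombuffer(payload[:n], dtype=np.uint8).copy()
        slots = np.frombuffer(payload[n : n + 8 * n_samples], dtype=np.int64)
        vals = np.frombuffer(payload[n + 8 * n_samples :], dtype=np.int64)
        row_sa = np.full(n, -1, dtype=np.int64)
        row_sa[slots] = vals
        counts_before, occ = _rank_tables(bwt_codes)
        return cls(
            bwt_codes=bwt_codes,
            counts_before=counts_before,
            occ=occ,
            row_sa=row_sa,
            sample_rate=int(header["sample_rate"]),
            text_length=n,
            chunk_id=int(header["chunk_id"]),
            manifest=StoreManifest.from_dict(header["manifest"]),
        )


def _rank_tables(bwt_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(bwt_codes)
    occ = np.zeros((n + 1, N_SYMBOLS), dtype=np.int32)
    for c in range(N_SYMBOLS):
        occ[1:, c] = np.cumsum((bwt_codes == c).astype(np.int32))
    totals = occ[n].astype(np.int64)
    counts_before = np.zeros(N_SYMBOLS + 1, dtype=np.int64)
    np.cumsum(totals, out=counts_before[1:])
    return counts_before, occ


def build_fm_index(
    store: ReadStore, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> FMIndexBundle:
    """Build the FM-index bundle for one read-store chunk."""
    if sample_rate < 1:
        raise ValueError("sample_rate must be >= 1")
    codes = encode_text(store.text)
    n = len(codes)
    sa = suffix_array(codes)
    bwt_codes = codes[(sa - 1) % n].astype(np.uint8)
    counts_before, occ = _rank_tables(bwt_codes)
    row_sa = np.where(sa % sample_rate == 0, sa, -1)
    return FMIndexBundle(
        bwt_codes=bwt_codes,
        counts_before=counts_before,
        occ=occ,
        row_sa=row_sa,
        sample_rate=sample_rate,
        text_length=n,
        chunk_id=store.chunk_id,
        manifest=store.manifest(),
    )


@dataclass
class IndexSet:
    """All chunks of one indexed read set, searched and merged together."""

    bundles: list[FMIndexBundle]

    def __post_init__(self) -> None:
        if not self.bundles:
            raise ValueError("empty index set")
        self.bundles = sorted(self.bundles, key=lambda b: b.chunk_id)
        ids = [b.chunk_id for b in self.bundles]
        if ids != list(range(len(ids))):
            raise ValueError(f"chunk ids not dense from 0: {ids}")
        expect = 0
        for b in self.bundles:
            if b.manifest.global_ordinal_offset != expect:
                raise ValueError("chunk ordinal ranges are not contiguous")
            expect += b.manifest.n_reads

    @property
    def paired(self) -> bool:
        return self.bundles[0].manifest.paired

    @property
    def n_reads(self) -> int:
        return sum(b.manifest.n_reads for b in self.bundles)

    @classmethod
    def from_store(
        cls,
        store: ReadStore,
        n_chunks: int = 1,
        sample_rate: int = DEFAULT_SAMPLE_RATE,
    ) -> "IndexSet":
        chunks = split_chunks(store, n_chunks) if n_chunks > 1 else [store]
        return cls([build_fm_index(c, sample_rate) for c in chunks])

    def save(self, prefix: Union[str, Path]) -> list[Path]:
        paths = []
        for b in self.bundles:
            p = Path(f"{prefix}.{b.chunk_id}.fmi")
            b.save(p)
            paths.append(p)
        return paths

    @classmethod
    def load(cls, prefix: Union[str, Path]) -> "IndexSet":
        prefix = Path(prefix)
        stem = prefix.name
        paths = sorted(
            prefix.parent.glob(stem + ".*.fmi"),
            key=lambda p: int(p.name[len(stem) + 1 : -4]),
        )
        if not paths:
            raise FileNotFoundError(f"no index files matching {prefix}.*.fmi")
        return cls([FMIndexBundle.load(p) for p in paths])
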