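"""The core query engine: k-mer generation, filtering, search, collation.

A query search runs in four steps:

1. **k-mer generation** — centered (every window covers the query middle,
   for SNP genotyping) or sliding (stepped window across the whole query,
   for target-sequence counting), with length ``k`` and step ``s``.
2. **filtering** — with ``ignore_nonunique_kmers``, any k-mer attributable
   to more than one query is dropped and the affected queries flagged.
3. **searching** — every retained k-mer is located in every index chunk;
   k-mers occurring more than ``max_occ`` times (summed over chunks) are
   skipped and their queries flagged.
4. **collation** — text positions become global read ordinals (reverse-
   complement copies map to their primary read), each query accumulates
   the *set* of matching reads (or pairs in ``paired_mode``), and with
   ``unique_reads`` a read claimed by two queries counts for neither.

Results are deterministic and independent of thread count and of whether
the read set was indexed as one monolithic index or as several chunks.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .fmindex import IndexSet, Overflow, encode_pattern
from .queries import QueryRecord, QuerySet
from .readstore import reverse_complement

CENTERED = "CENTERED"
SLIDING = "SLIDING"

READS = "READS"
PAIRS = "PAIRS"


@dataclass
class SearchSettings:
    """Search parameters.

    Defaults are the SNP-genotyping configuration (k=31, s=10, centered,
    max_occ=200, unique k-mers required); :meth:`pathogen_defaults` gives
    the target-sequence detection configuration (k=30, s=5, sliding,
    unique reads and unique k-mers, max_occ=2000).
    """

    k: int = 31
    s: int = 10
    mode: str = CENTERED
    max_occ: int = 200
    ignore_nonunique_kmers: bool = True
    unique_reads: bool = False
    paired_mode: bool = False
    search_rc: bool = True
    threads: int = 1

    @classmethod
    def pathogen_defaults(cls, **overrides) -> "SearchSettings":
        base = dict(
            k=30, s=5, mode=SLIDING, max_occ=2000,
            ignore_nonunique_kmers=True, unique_reads=True,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.s < 1:
            raise ValueError("step s must be >= 1")
        if self.mode not in (CENTERED, SLIDING):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.max_occ < 1:
            raise ValueError("max_occ must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.s > self.k:
            warnings.warn(
                f"step s={self.s} exceeds k={self.k}: some bases will never "
                "be covered by any k-mer",
                stacklevel=2,
            )


def kmers_centered(sequence: str, k: int, s: int) -> list[tuple[str, int]]:
    """k-mers whose window covers the central position ``len // 2``.

    Start offsets ascend from the leftmost feasible start by ``s``; the
    rightmost feasible start is always included so both extreme windows
    covering the center exist.
    """
    L = len(sequence)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    c = L // 2
    first = max(0, c - k + 1)
    last = min(c, L - k)
    starts = list(range(first, last + 1, s))
    if starts[-1] != last:
        starts.append(last)
    return [(sequence[i : i + k], i) for i in starts]


def kmers_sliding(sequence: str, k: int, s: int) -> list[tuple[str, int]]:
    """Stepped windows across the whole sequence, final window anchored at
    ``len - k`` so the 3' end is always searchable."""
    L = len(sequence)
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    starts = list(range(0, L - k + 1, s))
    if starts[-1] != L - k:
        starts.append(L - k)
    return [(sequence[i : i + k], i) for i in starts]


FWD = "+"
REV = "-"


@dataclass
class KmerMap:
    """k-mer -> owning queries, plus the uniqueness-filter bookkeeping."""

    entries: dict[str, frozenset]           # kmer -> {(query_id, orientation)}
    dropped_nonunique: set[str]
    flagged_queries: set[int]               # queries that lost >=1 k-mer to the filter
    query_ids: list[int]                    # the full query universe

    def query_ids_of(self, kmer: str) -> set[int]:
        return {qid for qid, _ in self.entries.get(kmer, ())}


def _generate(record: QueryRecord, settings: SearchSettings) -> list[tuple[str, int]]:
    gen = kmers_centered if settings.mode == CENTERED else kmers_sliding
    try:
        return gen(record.sequence, settings.k, settings.s)
    except ValueError as exc:
        raise ValueError(
            f"query {record.query_id} ({record.name or record.kind}): {exc}"
        ) from exc


def build_kmer_map(qs: QuerySet, settings: SearchSettings) -> KmerMap:
    """Steps 1+2: per-query k-mer sets, RC expansion, uniqueness filter."""
    settings.validate()
    raw: dict[str, set] = {}
    for rec in qs.records:
        kmers = {kmer for kmer, _ in _generate(rec, settings)}
        for kmer in kmers:
            raw.setdefault(kmer, set()).add((rec.query_id, FWD))
            if settings.search_rc:
                raw.setdefault(reverse_complement(kmer), set()).add((rec.query_id, REV))
    dropped: set[str] = set()
    flagged: set[int] = set()
    if settings.ignore_nonunique_kmers:
        for kmer, owners in raw.items():
            qids = {q for q, _ in owners}
            if len(qids) > 1:
                dropped.add(kmer)
                flagged |= qids
        for kmer in dropped:
            del raw[kmer]
    return KmerMap(
        entries={k: frozenset(v) for k, v in raw.items()},
        dropped_nonunique=dropped,
        flagged_queries=flagged,
        query_ids=list(qs.query_ids),
    )


RawHits = dict[tuple[str, int], Union[list[int], Overflow]]


def _search_chunk(bundle, kmers: Sequence[str], max_occ: int) -> RawHits:
    """Locate a batch of k-mers in one chunk (vectorized by k-mer length)."""
    out: RawHits = {}
    by_len: dict[int, list[str]] = {}
    for kmer in kmers:
        by_len.setdefault(len(kmer), []).append(kmer)
    for L, group in by_len.items():
        mat = np.stack([encode_pattern(km) for km in group])
        lo, hi = bundle.backward_search_batch(mat)
        sizes = hi - lo
        for i, kmer in enumerate(group):
            size = int(sizes[i])
            key = (kmer, bundle.chunk_id)
            if size == 0:
                out[key] = []
            elif size > max_occ:
                out[key] = Overflow(total=size)
            else:
                pos = bundle.locate_rows(np.arange(lo[i], hi[i]))
                out[key] = sorted(int(p) for p in pos)
    return out


def search_kmers(
    indexes: IndexSet, km: KmerMap, settings: SearchSettings
) -> RawHits:
    """Step 3: locate every retained k-mer in every chunk.

    Work is partitioned over ``settings.threads`` workers; results are
    keyed by (k-mer, chunk), so the merge is order-independent and the
    output is identical for any thread count.
    """
    settings.validate()
    kmers = sorted(km.entries)
    raw: RawHits = {}
    jobs = [
        (bundle, part)
        for bundle in indexes.bundles
        for part in np.array_split(np.asarray(kmers, dtype=object), settings.threads)
        if len(part)
    ]
    if settings.threads == 1 or len(jobs) <= 1:
        for bundle, part in jobs:
            raw.update(_search_chunk(bundle, list(part), settings.max_occ))
    else:
        with ThreadPoolExecutor(max_workers=settings.threads) as pool:
            futures = [
                pool.submit(_search_chunk, bundle, list(part), settings.max_occ)
                for bundle, part in jobs
            ]
            for fut in futures:
                raw.update(fut.result())
    return raw


@dataclass
class CountRow:
    count: int = 0
    flag_nonunique_kmer: bool = False
    flag_overmax_kmer: bool = False


@dataclass
class CountTable:
    """Per-query deduplicated read (or pair) counts with offending-k-mer flags."""

    rows: dict[int, CountRow]
    unit: str = READS

    def count(self, query_id: int) -> int:
        return self.rows[query_id].count

    def to_tsv(self) -> str:
        lines = [f"#unit={self.unit}", "query_id\tcount\tflag_nonunique_kmer\tflag_overmax_kmer"]
        for qid in sorted(self.rows):
            r = self.rows[qid]
            lines.append(
                f"{qid}\t{r.count}\t{int(r.flag_nonunique_kmer)}\t{int(r.flag_overmax_kmer)}"
            )
        return "\n".join(lines) + "\n"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.unit == other.unit
            and self.rows == other.rows
        )


def collate(
    raw_hits: RawHits,
    indexes: IndexSet,
    km: KmerMap,
    settings: SearchSettings,
) -> CountTable:
    """Step 4: merge chunk hits into a deduplicated per-query count table."""
    settings.validate()
    if settings.paired_mode and not indexes.paired:
        raise ValueError("paired_mode requires a paired index")
    # global occurrence totals per k-mer (Overflow carries its exact count)
    totals: dict[str, int] = {}
    for (kmer, _cid), hits in raw_hits.items():
        n = hits.total if isinstance(hits, Overflow) else len(hits)
        totals[kmer] = totals.get(kmer, 0) + n
    overmax = {kmer for kmer, n in totals.items() if n > settings.max_occ}

    manifests = {b.chunk_id: b.manifest for b in indexes.bundles}
    unit_sets: dict[int, set[int]] = {qid: set() for qid in km.query_ids}
    overmax_flagged: set[int] = set()
    for kmer in overmax:
        overmax_flagged |= km.query_ids_of(kmer)
    for (kmer, cid), hits in sorted(raw_hits.items()):
        if kmer in overmax or isinstance(hits, Overflow) or not hits:
            continue
        ordinals, _offsets, _is_rc = manifests[cid].map_positions(np.asarray(hits))
        units = ordinals // 2 if settings.paired_mode else ordinals
        for qid in km.query_ids_of(kmer):
            unit_sets[qid].update(int(u) for u in units)

    if settings.unique_reads:
        claim: dict[int, int] = {}
        for qid, units in unit_sets.items():
            for u in units:
                claim[u] = claim.get(u, 0) + 1
        contested = {u for u, c in claim.items() if c > 1}
        if contested:
            for units in unit_sets.values():
                units -= contested

    rows = {
        qid: CountRow(
            count=len(unit_sets[qid]),
            flag_nonunique_kmer=qid in km.flagged_queries,
            flag_overmax_kmer=qid in overmax_flagged,
        )
        for qid in km.query_ids
    }
    return CountTable(rows=rows, unit=PAIRS if settings.paired_mode else READS)


def run_query_search(
    indexes: IndexSet, qs: QuerySet, settings: SearchSettings
) -> CountTable:
    """Generate, filter, search, and collate — the full four-step pipeline."""
    km = build_kmer_map(qs, settings)
    raw = search_kmers(indexes, km, settings)
    return collate(raw, indexes, km, settings)


def write_counts(qs: QuerySet, ct: CountTable, path: Union[str, Path]) -> None:
    """Write counts in the input-mirroring query format with appended columns."""
    from .queries import _HEADER, _MISSING  # shared column layout

    cols = _HEADER + ["count", "flag_nonunique_kmer", "flag_overmax_kmer"]
    with open(path, "w") as fh:
        fh.write(f"#unit={ct.unit}\n")
        fh.write("\t".join(cols) + "\n")
        for r in qs.records:
            row = ct.rows[r.query_id]
            fh.write(
                "\t".join(
                    [
                        str(r.query_id),
                        r.kind,
                        r.chrom if r.chrom is not None else _MISSING,
                        str(r.pos) if r.pos is not None else _MISSING,
                        r.ref_allele if r.ref_allele is not None else _MISSING,
                        r.alt_allele if r.alt_allele is not None else _MISSING,
                        r.name if r.name else _MISSING,
                        r.sequence,
                        str(row.count),
                        str(int(row.flag_nonunique_kmer)),
                        str(int(row.flag_overmax_kmer)),
                    ]
                )
                + "\n"
            )


def read_counts(path: Union[str, Path]) -> tuple[QuerySet, CountTable]:
    """Read back a :func:`write_counts` file."""
    from .queries import _HEADER, _MISSING

    cols = _HEADER + ["count", "flag_nonunique_kmer", "flag_overmax_kmer"]
    records = []
    rows: dict[int, CountRow] = {}
    with open(path) as fh:
        unit_line = fh.readline().strip()
        if not unit_line.startswith("#unit="):
            raise ValueError(f"{path}: missing #unit header")
        unit = unit_line.split("=", 1)[1]
        header = fh.readline().rstrip("\n").split("\t")
        if header != cols:
            raise ValueError(f"{path}: malformed counts header")
        for lineno, raw in enumerate(fh, start=3):
            if not raw.strip():
                continue
            p = raw.rstrip("\n").split("\t")
            if len(p) != len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} columns")
            qid = int(p[0])
            records.append(
                QueryRecord(
                    qid, p[1], p[7],
                    None if p[2] == _MISSING else p[2],
                    None if p[3] == _MISSING else int(p[3]),
                    None if p[4] == _MISSING else p[4],
                    None if p[5] == _MISSING else p[5],
                    "" if p[6] == _MISSING else p[6],
                )
            )
            rows[qid] = CountRow(int(p[8]), bool(int(p[9])), bool(int(p[10])))
    return QuerySet(records=records), CountTable(rows=rows, unit=unit)


@dataclass
class KsearchResult:
    """Per-k-mer counts plus the per-group over-threshold tally."""

    kmers: list[str]                       # deduplicated, first-seen order
    groups: dict[str, Optional[str]]       # kmer -> group label
    table: CountTable                      # query_id = index into ``kmers``
    threshold: int
    group_tallies: dict[str, int]          # group -> #k-mers with count > threshold

    def count(self, kmer: str) -> int:
        return self.table.rows[self.kmers.index(kmer)].count


def ksearch(
    indexes: IndexSet,
    kmers: Sequence[tuple[str, Optional[str]]],
    settings: SearchSettings,
    threshold: int = 3,
) -> KsearchResult:
    """Search raw k-mers directly: each k-mer is its own single-k-mer query.

    The per-group tally counts member k-mers whose deduplicated read count
    is strictly greater than ``threshold`` (presence/absence screening of
    e.g. gene-distinguishing k-mer panels).
    """
    order: list[str] = []
    groups: dict[str, Optional[str]] = {}
    for kmer, group in kmers:
        kmer = kmer.upper()
        if kmer not in groups:
            order.append(kmer)
            groups[kmer] = group
        elif groups[kmer] is None and group is not None:
            groups[kmer] = group

    entries: dict[str, set] = {}
    for qid, kmer in enumerate(order):
        entries.setdefault(kmer, set()).add((qid, FWD))
        if settings.search_rc:
            entries.setdefault(reverse_complement(kmer), set()).add((qid, REV))
    dropped: set[str] = set()
    flagged: set[int] = set()
    if settings.ignore_nonunique_kmers:
        for kmer, owners in entries.items():
            qids = {q for q, _ in owners}
            if len(qids) > 1:
                dropped.add(kmer)
                flagged |= qids
        for kmer in dropped:
            del entries[kmer]
    km = KmerMap(
        entries={k: frozenset(v) for k, v in entries.items()},
        dropped_nonunique=dropped,
        flagged_queries=flagged,
        query_ids=list(range(len(order))),
    )
    raw = search_kmers(indexes, km, settings)
    table = collate(raw, indexes, km, settings)
    tallies: dict[str, int] = {}
    for qid, kmer in enumerate(order):
        group = groups[kmer]
        if group is None:
            continue
        tallies.setdefault(group, 0)
        if table.rows[qid].count > threshold:
            tallies[group] += 1
    return KsearchResult(
        kmers=order, groups=groups, table=table,
        threshold=threshold, group_tallies=tallies,
    )
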