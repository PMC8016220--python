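"""Query generation: VCF+reference SNP pairs, FASTA records, raw k-mer lists.

A query is a named target sequence to be counted in the read index.  SNP
queries come in REF/ALT pairs of odd length ``2*flank + 1`` centered on
the variant position, so that a centered k-mer search interrogates both
alleles symmetrically.  Arbitrary sequences (e.g. pathogen genomes) become
SEQ queries.  Loci are 1-based at file boundaries (VCF convention) and
0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import cyvcf2
import pysam
from pyfaidx import Fasta

from .readstore import normalize_sequence

log = logging.getLogger(__name__)

DEFAULT_FLANK = 50

REF = "REF"
ALT = "ALT"
SEQ = "SEQ"
_KINDS = (REF, ALT, SEQ)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class QueryRecord:
    query_id: int
    kind: str  # REF | ALT | SEQ
    sequence: str
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 1-based variant position for REF/ALT
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown query kind {self.kind!r}")
        if not self.sequence:
            raise ValueError(f"query {self.query_id} has an empty sequence")


@dataclass
class QuerySet:
    records: list[QueryRecord] = field(default_factory=list)
    flank: Optional[int] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        ids = [r.query_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("query ids are not unique")
        if ids and sorted(ids) != list(range(len(ids))):
            raise ValueError("query ids are not dense from 0")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def query_ids(self) -> list[int]:
        return [r.query_id for r in self.records]

    def snp_pairs(self) -> list[tuple[QueryRecord, QueryRecord]]:
        """(REF, ALT) record pairs grouped by locus, sorted by (chrom, pos).

        Raises if any REF record lacks its ALT partner (or vice versa).
        """
        by_locus: dict[tuple[str, int], dict[str, QueryRecord]] = {}
        for r in self.records:
            if r.kind == SEQ:
                continue
            by_locus.setdefault((r.chrom, r.pos), {})[r.kind] = r
        pairs = []
        for locus in sorted(by_locus):
            d = by_locus[locus]
            if set(d) != {REF, ALT}:
                raise ValueError(
                    f"site {locus[0]}:{locus[1]} lacks a {'ALT' if REF in d else 'REF'} query"
                )
            pairs.append((d[REF], d[ALT]))
        return pairs


def queries_from_vcf(
    vcf_path: Union[str, Path],
    reference_fasta_path: Union[str, Path],
    flank: int = DEFAULT_FLANK,
) -> QuerySet:
    """REF/ALT query pairs for every biallelic SNP in a VCF.

    The REF sequence is ``reference[pos-flank .. pos+flank]`` (1-based
    inclusive, length ``2*flank+1``); the ALT sequence substitutes the alt
    allele at the central base.  Indels, multi-allelic records, and SNPs
    whose window runs off a contig end are skipped with a warning and
    counted in ``n_skipped``.  A REF allele disagreeing with the reference
    FASTA raises, naming the site.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    fasta = Fasta(str(reference_fasta_path), sequence_always_upper=True)
    records: list[QueryRecord] = []
    skipped = 0
    qid = 0
    for var in cyvcf2.VCF(str(vcf_path)):
        ref, alts = var.REF, var.ALT
        if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1 \
                or ref not in _ACGT or alts[0] not in _ACGT:
            log.warning("skipping non-SNP/multi-allelic record %s:%d", var.CHROM, var.POS)
            skipped += 1
            continue
        chrom, pos, alt = var.CHROM, var.POS, alts[0]
        contig_len = len(fasta[chrom])
        if pos - flank < 1 or pos + flank > contig_len:
            log.warning("skipping %s:%d: flank window outside contig", chrom, pos)
            skipped += 1
            continue
        window = str(fasta[chrom][pos - flank - 1 : pos + flank]).upper()
        center = window[flank]
        if center != ref:
            raise ValueError(
                f"REF allele mismatch at {chrom}:{pos}: VCF says {ref}, "
                f"reference FASTA has {center}"
            )
        alt_window = window[:flank] + alt + window[flank + 1 :]
        name = f"{chrom}:{pos}:{ref}>{alt}"
        records.append(QueryRecord(qid, REF, window, chrom, pos, ref, alt, name))
        records.append(QueryRecord(qid + 1, ALT, alt_window, chrom, pos, ref, alt, name))
        qid += 2
    return QuerySet(records=records, flank=flank, n_skipped=skipped)


def queries_from_fasta(fasta_path: Union[str, Path]) -> QuerySet:
    """One SEQ query per FASTA record (header token as name, U mapped to T)."""
    records: list[QueryRecord] = []
    with pysam.FastxFile(str(fasta_path)) as fh:
        for qid, rec in enumerate(fh):
            seq = normalize_sequence(rec.sequence or "", rec.name)
            records.append(QueryRecord(qid, SEQ, seq, name=rec.name))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    return QuerySet(records=records)


def read_kmer_list(path: Union[str, Path]) -> list[tuple[str, Optional[str]]]:
    """Parse a k-mer list: one k-mer per line, optional tab-separated group.

    k-mers are validated over {A,C,G,T}; errors name the line number.
    """
    out: list[tuple[str, Optional[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            kmer = parts[0].strip().upper()
            group = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            if not kmer or set(kmer) - _ACGT:
                raise ValueError(f"{path}:{lineno}: invalid k-mer {parts[0]!r}")
            out.append((kmer, group))
    if not out:
        raise ValueError(f"{path}: empty k-mer list")
    return out


_HEADER = ["query_id", "kind", "chrom", "pos", "ref", "alt", "name", "sequence"]
_MISSING = "."


def write_query_file(qs: QuerySet, path: Union[str, Path]) -> None:
    """Write the tab-separated query format (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for r in qs.records:
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
                    ]
                )
                + "\n"
            )


def read_query_file(path: Union[str, Path]) -> QuerySet:
    records: list[QueryRecord] = []
    seen_ids: set[int] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"{path}:1: malformed query-file header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_HEADER)} columns")
            try:
                qid = int(parts[0])
                kind = parts[1]
                chrom = None if parts[2] == _MISSING else parts[2]
                pos = None if parts[3] == _MISSING else int(parts[3])
                ref = None if parts[4] == _MISSING else parts[4]
                alt = None if parts[5] == _MISSING else parts[5]
                name = "" if parts[6] == _MISSING else parts[6]
                rec = QueryRecord(qid, kind, parts[7], chrom, pos, ref, alt, name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if qid in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicated query_id {qid}")
            seen_ids.add(qid)
            records.append(rec)
    return QuerySet(records=records)
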