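"""Genotype calls from REF/ALT read counts, and VCF output.

The calling rule is a minimum-read-count threshold: an allele is
*supported* when its deduplicated read count is at least ``min_count``.
Both alleles supported -> heterozygous 0/1; only the reference -> 0/0;
only the alternate -> 1/1; neither -> no-call ./. .  This totalizes the
strict-inequality rule triple by treating count == min_count as supported
and adding the no-call case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .queries import QuerySet
from .search import CountTable

HOM_REF = "0/0"
HET = "0/1"
HOM_ALT = "1/1"
NO_CALL = "./."

DEFAULT_MIN_COUNT = 3


def call_genotype(ref_count: int, alt_count: int, min_count: int) -> str:
    """Apply the minimum-count rule to one site's allele counts."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    ref_ok = ref_count >= min_count
    alt_ok = alt_count >= min_count
    if ref_ok and alt_ok:
        return HET
    if ref_ok:
        return HOM_REF
    if alt_ok:
        return HOM_ALT
    return NO_CALL


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype: str
    ref_count: int
    alt_count: int
    flag_nonunique_kmer: bool = False
    flag_overmax_kmer: bool = False


def calls_from_counts(
    ct: CountTable, qs: QuerySet, min_count: int = DEFAULT_MIN_COUNT
) -> list[GenotypeCall]:
    """One genotype call per REF/ALT query pair, sorted by (chrom, pos)."""
    calls = []
    for ref_rec, alt_rec in qs.snp_pairs():
        ref_row = ct.rows[ref_rec.query_id]
        alt_row = ct.rows[alt_rec.query_id]
        calls.append(
            GenotypeCall(
                chrom=ref_rec.chrom,
                pos=ref_rec.pos,
                ref_allele=ref_rec.ref_allele,
                alt_allele=alt_rec.alt_allele,
                genotype=call_genotype(ref_row.count, alt_row.count, min_count),
                ref_count=ref_row.count,
                alt_count=alt_row.count,
                flag_nonunique_kmer=ref_row.flag_nonunique_kmer
                or alt_row.flag_nonunique_kmer,
                flag_overmax_kmer=ref_row.flag_overmax_kmer
                or alt_row.flag_overmax_kmer,
            )
        )
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.3
##source=readprobe
##INFO=<ID=NONUNIQ_KMER,Number=0,Type=Flag,Description="A k-mer of this site was shared between queries and dropped">
##INFO=<ID=OVERMAX_KMER,Number=0,Type=Flag,Description="A k-mer of this site exceeded the maximum occurrence threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype from the minimum-read-count rule">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Deduplicated read counts for the REF and ALT queries">
"""


def write_vcf(
    calls: list[GenotypeCall],
    out_path: Union[str, Path],
    sample_name: str = "SAMPLE",
    min_count: int = DEFAULT_MIN_COUNT,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write genotype calls as VCF v4.3 (one record per site, GT:AD)."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos))
    contigs = dict(contig_lengths or {})
    for c in calls:
        contigs.setdefault(c.chrom, None)
    with open(out_path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"##readprobe_min_count={min_count}\n")
        for name in sorted(contigs):
            length = contigs[name]
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_name
            + "\n"
        )
        for c in calls:
            flags = []
            if c.flag_nonunique_kmer:
                flags.append("NONUNIQ_KMER")
            if c.flag_overmax_kmer:
                flags.append("OVERMAX_KMER")
            info = ";".join(flags) if flags else "."
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t.\t"
                f"{info}\tGT:AD\t{c.genotype}:{c.ref_count},{c.alt_count}\n"
            )


def counts_to_vcf(
    ct: CountTable,
    qs: QuerySet,
    min_count: int,
    out_path: Union[str, Path],
    sample_name: str = "SAMPLE",
) -> list[GenotypeCall]:
    """Genotype every REF/ALT pair in the count table and write a VCF."""
    calls = calls_from_counts(ct, qs, min_count)
    write_vcf(calls, out_path, sample_name=sample_name, min_count=min_count)
    return calls
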