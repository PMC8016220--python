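"""Synthetic data: genomes, planted diploid SNPs, reads, pathogen spike-ins.

This module generates the controlled inputs the rest of the package is
validated against: uniform random genomes, biallelic SNPs planted with
known diploid genotypes and a minimum spacing (so SNP queries never
overlap), uniform-coverage stranded reads with an i.i.d. substitution
error model, and pathogen reads spiked into a background read set at
exact counts.  Everything is reproducible from an integer seed; every
truth record needed to score a downstream result is returned alongside
the data.

The error model is substitution-only and qualities are constant — exact
k-mer matching treats an indel read like a heavily substituted read, so
substitutions alone exercise the k/s sensitivity trade-off, and qualities
are discarded at indexing anyway.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .readstore import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

DEFAULT_GENOTYPE_PROBS = (0.25, 0.5, 0.25)  # 0/0, 0/1, 1/1


def make_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. A/C/G/T string, reproducible by seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@dataclass(frozen=True)
class PlantedSnp:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "0/0" | "0/1" | "1/1"


@dataclass(frozen=True)
class ReadOrigin:
    name: str
    haplotype: int      # 0/1 for diploid, 0 for haploid
    position: int       # 0-based start on the haplotype
    strand: str         # "+" or "-"


@dataclass
class TruthSet:
    """Ground truth for scoring: planted SNPs and/or per-read origins."""

    snps: list[PlantedSnp] = field(default_factory=list)
    read_origins: list[ReadOrigin] = field(default_factory=list)

    def genotype_of(self, chrom: str, pos: int) -> str:
        for s in self.snps:
            if s.chrom == chrom and s.pos == pos:
                return s.genotype
        raise KeyError(f"no planted SNP at {chrom}:{pos}")


def plant_snps(
    genome: str,
    n_snps: int,
    seed: int,
    spacing: int = 101,
    edge_margin: int = 0,
    genotype_probs: Sequence[float] = DEFAULT_GENOTYPE_PROBS,
    chrom: str = "sim",
) -> tuple[str, str, TruthSet]:
    """Plant biallelic SNPs with diploid genotypes onto two haplotypes.

    Positions are drawn without replacement under a minimum ``spacing``
    (default 101 = one flank-50 query width, so SNP queries never
    overlap), and at least ``edge_margin`` bases from either contig end
    (set it to the query flank so every site admits a full centered
    query window).  For heterozygous sites the alt-carrying haplotype is
    chosen at random.  Returns (haplotype_A, haplotype_B, truth); the
    input genome is the reference: every planted REF allele equals the
    reference base.
    """
    L = len(genome)
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if n_snps > L:
        raise ValueError("more SNPs than genome positions")
    rng = np.random.default_rng(seed)
    # jittered grid: one site uniform within each of n equal slots, with the
    # jitter range reduced by `spacing` so consecutive sites always respect it
    usable = L - 2 * edge_margin
    if n_snps > 0 and (usable <= 0 or usable / n_snps < spacing):
        raise ValueError(
            f"cannot place {n_snps} SNPs with spacing {spacing} "
            f"(edge margin {edge_margin}) in {L} bases"
        )
    accepted: list[int] = []
    if n_snps > 0:
        w = usable / n_snps
        play = int(w) - spacing  # integer slack within each slot
        jitter = rng.integers(0, play + 1, size=n_snps)
        accepted = [
            edge_margin + int(i * w) + int(j) for i, j in enumerate(jitter)
        ]

    hap_a = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    hap_b = hap_a.copy()
    snps: list[PlantedSnp] = []
    gt_labels = ("0/0", "0/1", "1/1")
    for pos0 in accepted:
        ref = genome[pos0]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        gt = gt_labels[int(rng.choice(3, p=np.asarray(genotype_probs)))]
        alt_byte = ord(alt)
        if gt == "1/1":
            hap_a[pos0] = alt_byte
            hap_b[pos0] = alt_byte
        elif gt == "0/1":
            if rng.integers(0, 2):
                hap_a[pos0] = alt_byte
            else:
                hap_b[pos0] = alt_byte
        snps.append(PlantedSnp(chrom, pos0 + 1, ref, alt, gt))
    return (
        hap_a.tobytes().decode("ascii"),
        hap_b.tobytes().decode("ascii"),
        TruthSet(snps=snps),
    )


def write_truth_vcf(
    truth: TruthSet, path: Union[str, Path], contig_lengths: dict[str, int]
) -> None:
    """Write planted SNPs as a minimal VCF v4.3 (GT of the simulated sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n##source=readprobe-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Planted genotype">\n')
        for name in sorted(contig_lengths):
            fh.write(f"##contig=<ID={name},length={contig_lengths[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
        for s in sorted(truth.snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{s.genotype}\n"
            )


def _apply_errors(reads: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """i.i.d. substitutions: each errored base becomes one of the 3 others."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        orig = _BASE_INDEX[reads[mask]]
        shift = rng.integers(1, 4, size=n_err)
        reads[mask] = _BASES[(orig + shift) % 4]
    return reads


@dataclass
class SimReads:
    """Simulated reads plus their per-read origin truth."""

    records: list[tuple[str, str]]           # (name, sequence); interleaved if paired
    origins: list[ReadOrigin]
    paired: bool = False

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]


def simulate_reads(
    haplotypes: Sequence[str],
    read_length: int,
    *,
    depth: Optional[float] = None,
    n_reads: Optional[int] = None,
    error_rate: float = 0.0,
    paired: bool = False,
    fragment_length: Optional[int] = None,
    seed: int = 0,
    name_prefix: str = "read",
) -> SimReads:
    """Uniform-coverage stranded reads from one or two haplotypes.

    Exactly one of ``depth`` / ``n_reads`` must be given; with ``depth``,
    ``n_reads = round(depth * genome_length / read_length)`` (read count,
    also for paired data where two mates then cover one fragment each
    end).  Start positions, strand, and haplotype are uniform; minus-
    strand reads are emitted reverse-complemented.
    """
    if (depth is None) == (n_reads is None):
        raise ValueError("give exactly one of depth or n_reads")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    haps = [h.upper() for h in haplotypes]
    if len({len(h) for h in haps}) != 1:
        raise ValueError("haplotypes must have equal length")
    L = len(haps[0])
    if read_length > L:
        raise ValueError("read_length exceeds genome length")
    if n_reads is None:
        n_reads = int(round(depth * L / read_length))
    rng = np.random.default_rng(seed)
    hap_arrays = [np.frombuffer(h.encode("ascii"), dtype=np.uint8) for h in haps]

    records: list[tuple[str, str]] = []
    origins: list[ReadOrigin] = []
    if paired:
        if fragment_length is None or fragment_length < read_length:
            raise ValueError("paired mode needs fragment_length >= read_length")
        if fragment_length > L:
            raise ValueError("fragment_length exceeds genome length")
        n_pairs = (n_reads + 1) // 2
        starts = rng.integers(0, L - fragment_length + 1, size=n_pairs)
        hap_idx = rng.integers(0, len(haps), size=n_pairs)
        strands = rng.integers(0, 2, size=n_pairs)
        for i in range(n_pairs):
            h, p, minus = int(hap_idx[i]), int(starts[i]), bool(strands[i])
            frag = hap_arrays[h][p : p + fragment_length].copy()
            frag = _apply_errors(frag.reshape(1, -1), error_rate, rng)[0]
            fwd = frag[:read_length].tobytes().decode("ascii")
            rev = reverse_complement(frag[-read_length:].tobytes().decode("ascii"))
            r1, r2 = (rev, fwd) if minus else (fwd, rev)
            strand = "-" if minus else "+"
            records.append((f"{name_prefix}{i}/1", r1))
            records.append((f"{name_prefix}{i}/2", r2))
            origins.append(ReadOrigin(f"{name_prefix}{i}/1", h, p, strand))
            origins.append(ReadOrigin(f"{name_prefix}{i}/2", h, p, strand))
        return SimReads(records=records, origins=origins, paired=True)

    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    hap_idx = rng.integers(0, len(haps), size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    gather = starts[:, None] + np.arange(read_length)[None, :]
    reads = np.empty((n_reads, read_length), dtype=np.uint8)
    for h, arr in enumerate(hap_arrays):
        sel = hap_idx == h
        reads[sel] = arr[gather[sel]]
    reads = _apply_errors(reads, error_rate, rng)
    for i in range(n_reads):
        seq = reads[i].tobytes().decode("ascii")
        minus = bool(strands[i])
        if minus:
            seq = reverse_complement(seq)
        name = f"{name_prefix}{i}"
        records.append((name, seq))
        origins.append(
            ReadOrigin(name, int(hap_idx[i]), int(starts[i]), "-" if minus else "+")
        )
    return SimReads(records=records, origins=origins)


def write_fastq(records: Sequence[tuple[str, str]], path: Union[str, Path]) -> None:
    """Write (name, seq) records as FASTQ with a constant quality string."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_origins_tsv(origins: Sequence[ReadOrigin], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("name\thaplotype\tposition\tstrand\n")
        for o in origins:
            fh.write(f"{o.name}\t{o.haplotype}\t{o.position}\t{o.strand}\n")


def spike_in_records(
    background: Sequence[tuple[str, str]],
    pathogen_genome: str,
    n_reads: int,
    read_length: int,
    *,
    error_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "spike",
) -> tuple[list[tuple[str, str]], list[str]]:
    """Append exactly ``n_reads`` pathogen reads to a background read list.

    Returns (combined records, names of the spiked reads).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    combined = list(background)
    if n_reads == 0:
        return combined, []
    sim = simulate_reads(
        [pathogen_genome],
        read_length,
        n_reads=n_reads,
        error_rate=error_rate,
        seed=seed,
        name_prefix=name_prefix,
    )
    combined.extend(sim.records)
    return combined, [name for name, _ in sim.records]


def spike_in(
    background_fastq: Union[str, Path],
    pathogen_genome: str,
    n_reads: int,
    read_length: int,
    out_path: Union[str, Path],
    *,
    error_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "spike",
) -> list[str]:
    """File-level spike-in: background FASTQ + n pathogen reads -> FASTQ.

    Returns the names of the spiked read records (the detection truth).
    """
    import pysam

    with pysam.FastxFile(str(background_fastq)) as fh:
        background = [(rec.name, rec.sequence or "") for rec in fh]
    combined, spiked = spike_in_records(
        background, pathogen_genome, n_reads, read_length,
        error_rate=error_rate, seed=seed, name_prefix=name_prefix,
    )
    write_fastq(combined, out_path)
    return spiked
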