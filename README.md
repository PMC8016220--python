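# readprobe

**Reverse mapping for short-read sequencing data.** Instead of aligning
reads to a reference genome, `readprobe` builds an FM-index of the *raw
reads* themselves and then counts flexible k-mer queries against that
index — answering "how many reads in this sample contain this allele /
this pathogen sequence / this exact k-mer?" without any alignment step.

It is aimed at people who have FASTQ files and targeted questions:
genotyping a panel of known biallelic SNPs, screening a sample for a
set of viral genomes, or counting a curated panel of gene-distinguishing
k-mers — all directly from the reads, re-queryable with new targets
without re-indexing.

## How it works

**Index.** Reads are stripped of qualities, uppercased, and concatenated
into one text `r_1 $ r_2 $ … r_n $` with a sentinel `$` between reads.
From the suffix array of that text the Burrows–Wheeler transform
`BWT[i] = T[SA[i]−1]` is built, plus a per-symbol occurrence (rank) table
and a subsampled suffix array. Backward search then narrows the
suffix-array interval of a pattern `P` one symbol at a time,

```
lo ← C[c] + Occ(c, lo),   hi ← C[c] + Occ(c, hi)      (c = P[m−1] … P[0])
```

so counting all exact occurrences of a k-mer costs O(k) rank lookups,
and each occurrence is located by walking the LF-mapping to the nearest
sampled suffix-array slot. Because query k-mers never contain `$`, a
match can never span two reads. Large read sets can be split into
chunks, indexed independently, and searched together.

**Query.** Queries come from three sources: a VCF + reference FASTA
(REF/ALT sequence pairs of length `2·flank+1` centered on each biallelic
SNP), arbitrary FASTA records (e.g. pathogen genomes), or plain k-mer
lists. Per query, k-mers of length `k` at step `s` are generated either
*centered* (every window covers the query midpoint — the SNP) or
*sliding* (stepped across the whole sequence, both ends anchored).

**Count.** k-mers shared between queries can be dropped
(`ignore_nonunique_kmers`), and k-mers occurring more than `max_occ`
times are skipped; both conditions flag the affected queries
("offending k-mers"). Hits are translated back to read IDs (reverse-
complement hits map to the primary read), deduplicated — a read matched
by many k-mers of a query counts once — optionally collapsed to read
pairs, and optionally subjected to `unique_reads` (a read claimed by two
queries counts for neither). Results are byte-identical regardless of
thread count or chunking.

**Genotype.** REF/ALT count pairs become genotype calls through a
minimum-count rule: allele *supported* ⇔ count ≥ `minCount`; both
supported → `0/1`, only REF → `0/0`, only ALT → `1/1`, neither → `./.`,
written as VCF v4.3 with `GT:AD`.

## Worked example

Simulate a 20 kb diploid sample with 20 planted SNPs at 30× coverage,
index it, and genotype it — all from the shell:

```bash
readprobe simulate genome --length 20000 --seed 11 --out ref.fa
readprobe simulate snps --genome ref.fa --n-snps 20 --seed 12 \
    --spacing 150 --edge-margin 50 --out-prefix sim
readprobe simulate reads --haplotype sim.hapA.fa --haplotype sim.hapB.fa \
    --depth 30 --read-length 100 --seed 13 --out reads.fq
readprobe index reads.fq --out idx --chunks 2
readprobe vcf2query --vcf sim.truth.vcf --ref ref.fa --flank 50 --out queries.tsv
readprobe search --index idx --queries queries.tsv -k 31 -s 10 --max-occ 200 \
    --out counts.tsv
readprobe genotype --counts counts.tsv --min-count 3 --out sample.vcf
```

`counts.tsv` mirrors the query file with appended counts — here the REF
and ALT queries of the first site were each seen in a balanced number of
distinct reads, as expected for a heterozygote at 30×:

```
query_id  kind  chrom  pos  ref  alt  name          ...  count  flags
0         REF   sim    569  G    T    sim:569:G>T   ...  20     0  0
1         ALT   sim    569  G    T    sim:569:G>T   ...  16     0  0
```

and `sample.vcf` holds the calls:

```
#CHROM  POS   ID  REF  ALT  QUAL  FILTER  INFO  FORMAT  SAMPLE
sim     569   .   G    T    .     .       .     GT:AD   0/1:20,16
sim     3836  .   A    T    .     .       .     GT:AD   1/1:0,29
```

Comparing against the planted truth: 20/20 genotypes concordant.

The same engine drives pathogen screening (`fasta2query` + sliding
search with `k=30 s=5 --unique-reads --unique-kmers`) and direct k-mer
panels (`ksearch --kmers panel.txt --threshold 3`, which also tallies,
per group label, the k-mers seen in more than `threshold` reads).

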