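# allelex

Allele-specific expression of somatic mutations from RNA-seq, via
tumor-specific dual-contig reference genomes.

## The problem

Tumor genomes carry a mix of driver mutations, passengers, and variants in
genes the tumor never transcribes. DNA sequencing alone cannot tell these
apart. RNA-seq can — *if* reads can be reliably assigned to the mutant or
wild-type allele, which standard reference alignment does poorly for small
insertions and deletions: indel-bearing reads mismatch the reference and are
misplaced or dropped.

`allelex` sidesteps the problem by building, per tumor sample, a small custom
reference containing **two contigs per mutated gene**: the wild-type genomic
sequence (`>GENE`) and the same sequence with all of the sample's mutations
spliced in (`>GENE_Mut`). Reads aligned against this reference sort
themselves onto the haplotype they support, so allele support is determined
by *which contig* a read lands on — equally well for SNVs and indels. Because
the reference holds only mutated genes, it is orders of magnitude smaller
than a whole genome, and alignment is fast.

From the aligned, filtered reads, each mutation gets wild-type support `w`,
mutant support `v`, and an RNA mutant-allele frequency

```
RNA MAF = v / (w + v)
```

and is classified by total read count `t = w + v`:

| group | rule | meaning |
|---|---|---|
| N-ex | `t < 3` | neither allele expressed |
| discarded | `3 ≤ t ≤ 9` | too few reads to call reliably |
| V-ex | `t > 9` and MAF ≥ 2.5% | mutant allele expressed |
| W-ex | `t > 9` and MAF < 2.5% | only the wild-type allele expressed |

For indels, support is counted with position-averaged pileup depth: a
deletion of length L averages depth over the L deleted bases on the
wild-type contig and reads the first non-deleted base on the mutant contig;
an insertion mirrors this. Multiple mutations in one gene are applied with a
shifting algorithm that tracks the cumulative coordinate offset from
upstream indels, and the resulting wild-type/mutant position map is written
as an index file consumed by the counter.

Intended users: cancer genomics groups with matched somatic mutation calls
(TSV or MAF) and RNA-seq for the same samples, who want per-mutation
expression groups and DNA-vs-RNA allele-frequency profiles.

## Pipeline

```
allelex build     --fasta ref.fa --gtf ann.gtf --mutations muts.tsv --sample S1 --out dir/
  (align reads to dir/S1.reference.fa with your favorite spliced aligner, e.g.
   bowtie2-build + tophat2/HISAT2 — external to this package)
allelex filter    --in aligned.bam --out filtered.bam        # duplicates, mapq >= 50, singletons
allelex count     --bam filtered.bam --index dir/S1.index.tsv --out counts.tsv
allelex classify  --counts counts.tsv --mutations muts.tsv --sample S1 --out profile.tsv
```

or all at once from a YAML config with a manifest of digests, thresholds and
per-stage counts:

```bash
allelex run --config run.yaml
```

`allelex simulate` generates a complete synthetic data set (genome, GTF,
mutation table, and truth-placed paired-end alignments over a planted
wild-type/mutant mixture), so the whole pipeline runs without any external
aligner or download.

## Worked example

```bash
allelex simulate --out sim/ --scenario scenario.yaml --seed 17
allelex run --config run.yaml
```

with four genes (planted mutant fractions 0.5, 0.0, 1.0, 0.5; depth 120)
prints per-stage counts and writes `S1.profile.tsv`:

```
sample  gene  chrom  pos   ref  alt  type  dna_af  wt_reads  mut_reads  total  rna_maf  group
S1      G001  chr1   669   AGG  -    DEL   0.5     63.0      57.0       120.0  0.475    V_EX
S1      G001  chr1   792   T    A    SNV   0.5     102.0     100.0      202.0  0.495    V_EX
S1      G002  chr2   396   AAT  -    DEL   0.0     120.0     0.0        120.0  0.0      W_EX
S1      G002  chr2   1216  G    A    SNV   0.0     120.0     0.0        120.0  0.0      W_EX
S1      G003  chr3   447   A    C    SNV   1.0     0.0       120.0      120.0  1.0      V_EX
...
```

Genes with a planted 50% mixture come out near MAF 0.5 (V-ex), the pure
wild-type gene has MAF 0 (W-ex), and the pure mutant gene MAF 1 — including
the deletions, which is the point of the dual-contig design. The summary
table aggregates group counts and fractions per sample and pooled.

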