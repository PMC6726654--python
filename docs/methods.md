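# Methods

## Model and procedure

`allelex` quantifies allele-specific expression of somatic mutations by
alignment to a per-sample *dual-contig* reference rather than by per-base
inspection of mismatches against a standard genome. For every gene carrying
at least one mutation in the sample, the reference holds the gene's
wild-type genomic sequence and a mutant copy with all of that sample's
mutations spliced in. A read drawn from the mutant haplotype matches the
mutant contig exactly (indels included) and is expected to align there;
allele assignment is therefore positional — the contig name — and is equally
reliable for SNVs and small indels. The assumption underneath is that the
aligner, given two contigs differing only at the mutated sites, places a
read on the contig it matches best; reads equally consistent with both
contigs (those not overlapping any mutation) contribute to neither allele
count because counting happens only at the indexed mutation positions.

### Reference construction and the coordinate index

Gene sequences are the full genomic span of the GTF `gene` feature, introns
included, taken on the reference (+) strand. The annotation never states
whether transcripts should be concatenated instead; the full span keeps the
wild-type→mutant coordinate map affine per gene and lets a spliced aligner
handle introns, which is why we chose it. Strand is recorded but sequences
are not reverse-complemented (aligners handle both orientations).

Mutations are applied left-to-right while tracking the cumulative length
offset (`shift`) contributed by upstream indels. For each mutation the index
records its 1-based position on both contigs:

* SNV at wild-type position `p` → mutant position `p + shift`;
* deletion starting at `p` → mutant position `p + shift` is the first
  *non-deleted* base;
* insertion anchored at `p` (the base 5′ of the inserted sequence) → mutant
  position `p + shift + 1` is the first *inserted* base.

`shift` stored per entry is the offset in force *before* that mutation's own
edit. All coordinates in files are 1-based and fully closed, matching
MAF/VCF-style conventions.

Overlapping mutations within a gene are a hard error: composition of
overlapping edits is undefined. The one co-location we accept is an SNV and
an insertion anchored at the same base — the SNV rewrites the base, the
insertion lands after it, and the composition is unambiguous. An insertion
anchored at a deleted base (including the deletion's boundary base) is
rejected, since the anchor no longer exists on the mutant haplotype.
Reference alleles are validated against the extracted sequence by default
(`check_ref`), which catches 0/1-based off-by-one errors in upstream calls
immediately; an override exists for deliberately inconsistent inputs.

Duplicate gene symbols in the annotation get a `#k` ordinal suffix
(`GX`, `GX#2`, …) so contig headers map one-to-one onto gene models;
mutations are resolved to the unique candidate model containing their
coordinates, and unresolvable ones are routed to a skipped-mutations table
with a reason rather than aborting the build.

### Alignment filtering

Three predicates, in order: (1) drop records flagged as PCR duplicates —
optionally also marking duplicates internally by keep-first on
(contig, position, orientation, CIGAR, mate position), a deterministic
stand-in for external duplicate markers that we use when input carries no
flags; the external tools' base-quality tie-breaking is deliberately not
reproduced, so ties keep the first record seen; (2) keep uniquely aligned
reads: mapping quality ≥ 50, no secondary or unmapped records; (3) drop
singletons (paired reads whose mate is unmapped). Unpaired reads pass the
singleton step untouched, so it self-disables for single-end data. The
filters are lazy, order-preserving, idempotent, and monotone in the mapping
quality cutoff.

### Allele counting

Depth at a position counts records whose CIGAR places an aligned
(M/=/X) base there; deletions (D) and skips (N) inside a read span
positions without covering them. Depth is accumulated as interval endpoints
and materialised with a cumulative sum, which makes whole-sample counting
linear in the number of CIGAR blocks. Per mutation:

* SNV — wild-type support = depth at `wt_pos` on the wild-type contig,
  mutant support = depth at `mut_pos` on the mutant contig;
* deletion of length L — wild-type support = *mean* depth over the L deleted
  bases; mutant support = depth at the first non-deleted base;
* insertion of length L — mutant support = mean depth over the L inserted
  bases; wild-type support = depth at `wt_pos + 1`, the first non-inserted
  base. The counted side/contig for that phrase is genuinely ambiguous; we
  read it as the base immediately after the anchor on the wild-type contig,
  mirroring the deletion rule.

Averaged depths stay fractional end to end — no rounding anywhere. The RNA
mutant-allele frequency is `mut / (wt + mut)`, undefined (NA) at zero total.
Each mate of a pair is counted as its own record (per-record pileup
semantics); an optional strict mode additionally requires the aligned read
base at the counted position to equal the contig base, off by default.

### Classification

With total `t` (possibly fractional) and the defaults
`discard_min = 3`, `discard_max = 9`, `vex_min_maf = 0.025`:
`t < 3` → N-ex; `3 ≤ t ≤ 9` → discarded (band inclusive on both ends);
otherwise V-ex if MAF ≥ 2.5% (threshold inclusive on the V-ex side, a choice
— the inequality direction at exactly 2.5% is not independently fixed) else
W-ex. W-ex needs no separate `wt > 0` test: `t > 9` with MAF < 2.5% already
implies substantial wild-type support. The four predicates partition all
(t, MAF) values; classification is a pure function of counts and config.
Mutations seen in several samples are classified independently per sample.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_mapq` | 50 | phred-scaled mapq | retains uniquely aligned reads under common aligner conventions |
| `discard_min`, `discard_max` | 3, 9 | reads | band where misalignment/shallow depth could flip a call |
| `vex_min_maf` | 0.025 | fraction | separates residual noise from genuine mutant expression |
| `check_ref` | on | — | fail fast on coordinate-convention mismatches |

## The simulator

The simulator emulates what the pipeline consumes in practice: per-gene
wild-type/mutant haplotype pairs sampled at a planted mutant fraction
`f`, paired-end reads of configurable length and depth, substitution
sequencing errors, PCR-duplicate copies (flagged), and a two-point mapping
quality model. Reads are placed at their *true* contig offsets with pure
match CIGARs (oracle placement): under the dual-contig design allele
membership is positional, so this exercises exactly the coordinate and
depth arithmetic the counter consumes while removing the external-aligner
dependency. Mixture and depth are keyed per gene, because all mutations of
one gene live on one haplotype pair and share a mutant fraction; the
simulated DNA allele frequency is set to `f` (a clonal-fraction reading).

Defaults represent a mid-depth bulk RNA-seq experiment: 100 bp paired reads,
depth 100 fragments per locus, error rate 1e-3, balanced mixture 0.5. The
first mate always covers the mutation's counted positions and the second
sits one insert gap downstream, so realised totals fall in
[depth, 2×depth].

What the simulator does **not** model — and what passing tests therefore do
not demonstrate about real data: splicing (reads are contiguous), aligner
mismapping and multi-mapping between homologous genes, fragment-length
variation, base-quality structure, strand bias, and reference bias of a real
aligner confronted with indel-bearing reads. The analytic expectation used
as the end-to-end oracle labels a mutation "uncertain" when its planted
fraction lies within three binomial standard errors of the V/W threshold or
its depth puts the realised total astride a band edge; agreement is only
asserted away from those boundaries.

## Numerical and design choices

* Depth vectors use 64-bit integer cumulative sums; averaged indel depths
  are IEEE doubles. No tolerance is needed anywhere in the core — all
  comparisons are exact arithmetic on counts.
* Deterministic ordering everywhere: mutations sort by (sample, gene, pos),
  contig pairs follow annotation order, simulated records are
  coordinate-sorted with a stable name tie-break; identical seeds give
  byte-identical outputs.
* Degenerate inputs: zero-coverage mutations get MAF = NA and fall in N-ex;
  a mutation whose contigs are absent from the alignment file gets zero
  counts with a warning, but an alignment file sharing *no* contig with the
  index raises a reference-mismatch error; an insertion anchored at the last
  base of a gene counts wild-type support at a position one past the contig
  and receives 0 there.
* The per-sample pipeline is resumable from intermediate artifacts; the
  manifest records input digests and every threshold actually used.

## Known limitations

* Gene-span contigs duplicate sequence between overlapping genes; a read
  from a shared exon can align to both genes' contigs and be counted twice
  (once per gene's index entries). The tool mirrors the per-gene design and
  does not deduplicate across genes.
* No phasing: all mutations of a gene are placed on one mutant haplotype.
  Two mutations of the same gene on different parental haplotypes are not
  representable.
* Structural variants and multi-allelic sites per sample are out of scope;
  overlapping edits are rejected rather than composed.
* Allele assignment trusts the aligner's contig choice; the strict
  base-checking mode tightens this but cannot recover reads the aligner
  never placed.
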