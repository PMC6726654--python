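"""Synthetic fixtures: genome, annotation, mutations and reads.

The simulator emulates the inputs the pipeline sees in practice —
paired-end RNA-seq fragments drawn from a wild-type/mutant haplotype
pair at a planted mixture fraction — without invoking an aligner.
Reads are placed at their *true* offsets on the contig they were drawn
from (oracle placement) with pure-match CIGARs: under the dual-contig
design allele membership is positional, not CIGAR-encoded, so oracle
placement exercises exactly the coordinate arithmetic the counter
consumes.

Knobs: per-locus fragment depth, read length, substitution sequencing
error rate, PCR duplicate rate (duplicates are emitted as flagged extra
copies) and a two-point mapping-quality model.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .alignment_filter import FilterConfig, FilterStats, filter_alignments
from .allele_counter import count_sample
from .classifier import ClassifierConfig, DEFAULT_CONFIG, build_profile
from .errors import CapacityError, ConfigError
from .genome_builder import (
    GeneModel,
    GenePair,
    MutationIndexEntry,
    MutationRecord,
    build_custom_reference,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimScenario:
    """One simulated study condition.

    ``mixture`` and ``depth`` may be scalars applied to every gene or
    mappings keyed by gene name, so scenarios can plant different
    mutant fractions (and silent, zero-coverage genes) side by side.
    ``mapq`` is (high, low, fraction_low): each read draws the low
    mapping quality with the given probability.
    """

    n_genes: int = 10
    gene_length: int = 2000
    flank: int = 200
    mutations_per_gene: Mapping[str, int] = field(default_factory=lambda: {"SNV": 1})
    indel_length: int = 3
    mixture: Union[float, Mapping[str, float]] = 0.5
    depth: Union[int, Mapping[str, int]] = 100
    read_length: int = 100
    insert_gap: int = 20
    error_rate: float = 0.001
    dup_rate: float = 0.0
    mapq: tuple = (60, 0, 0.0)
    sample: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length >= self.gene_length:
            raise ConfigError("read_length must be smaller than gene_length")
        for name, rate in (("error_rate", self.error_rate), ("dup_rate", self.dup_rate)):
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must be in [0, 1)")
        if isinstance(self.mixture, float) and not 0.0 <= self.mixture <= 1.0:
            raise ConfigError("mixture must be in [0, 1]")
        if any(t not in ("SNV", "INS", "DEL") for t in self.mutations_per_gene):
            raise ConfigError("mutations_per_gene keys must be SNV/INS/DEL")

    def fraction_for(self, gene: str) -> float:
        if isinstance(self.mixture, Mapping):
            return float(self.mixture[gene])
        return float(self.mixture)

    def depth_for(self, gene: str) -> int:
        if isinstance(self.depth, Mapping):
            return int(self.depth[gene])
        return int(self.depth)


def simulate_reference(
    scenario: SimScenario,
) -> tuple[dict[str, str], list[GeneModel], list[MutationRecord]]:
    """Generate a random genome, one gene model per chromosome, and mutations.

    Mutations are placed non-overlapping inside each gene span with a
    read-length margin from the gene edges, and their reference alleles
    are read off the generated sequence, so the builder's reference
    check passes by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0xA11E]))
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    mutations: list[MutationRecord] = []
    chrom_len = scenario.gene_length + 2 * scenario.flank
    margin = scenario.read_length + scenario.indel_length

    n_per_gene = sum(scenario.mutations_per_gene.values())
    span = scenario.gene_length - 2 * margin
    if span < n_per_gene * (scenario.indel_length + 4) * 2:
        raise CapacityError(
            f"cannot place {n_per_gene} mutations in a usable span of {span} bases"
        )

    for g in range(scenario.n_genes):
        chrom = f"chr{g + 1}"
        gene = f"G{g + 1:03d}"
        seq = "".join(rng.choice(_BASES, size=chrom_len))
        genome[chrom] = seq
        start = scenario.flank + 1
        end = scenario.flank + scenario.gene_length
        models.append(GeneModel(gene=gene, chrom=chrom, strand="+", start=start, end=end))

        occupied: list[tuple[int, int]] = []
        lo, hi = start + margin, end - margin
        dna_af = scenario.fraction_for(gene)
        for mtype in ("SNV", "DEL", "INS"):
            for _ in range(scenario.mutations_per_gene.get(mtype, 0)):
                pos = _place(rng, lo, hi, scenario.indel_length, occupied)
                if mtype == "SNV":
                    ref = seq[pos - 1]
                    alt = str(rng.choice(_BASES[_BASES != ref]))
                elif mtype == "DEL":
                    ref = seq[pos - 1: pos - 1 + scenario.indel_length]
                    alt = "-"
                else:
                    ref = "-"
                    alt = "".join(rng.choice(_BASES, size=scenario.indel_length))
                mutations.append(MutationRecord(
                    sample_id=scenario.sample, gene=gene, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, mtype=mtype, dna_af=dna_af,
                ))
    mutations.sort(key=lambda m: (m.sample_id, m.gene, m.pos))
    return genome, models, mutations


def _place(rng, lo: int, hi: int, indel_length: int, occupied: list[tuple[int, int]]) -> int:
    pad = indel_length + 2  # keeps edits apart so no pair can overlap
    for _ in range(1000):
        pos = int(rng.integers(lo, hi + 1))
        if all(abs(pos - s) > pad and abs(pos - e) > pad for s, e in occupied):
            occupied.append((pos, pos + indel_length))
            return pos
    raise CapacityError("could not place a mutation without overlap after 1000 tries")


def simulate_alignments(
    pairs: Sequence[GenePair],
    entries: Sequence[MutationIndexEntry],
    scenario: SimScenario,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Draw paired-end fragments over every mutation locus.

    For each index entry, ``depth`` fragments are generated; each comes
    from the mutant haplotype with the gene's planted probability ``f``
    and from the wild-type haplotype otherwise.  The first mate always
    covers the counted position(s) of its haplotype; the second mate
    sits one insert gap downstream (clamped to the contig).  Records
    come back coordinate-sorted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0x5EAD]))
    by_gene = {p.gene: p for p in pairs}
    refs = []
    for p in pairs:
        refs.append({"SN": p.wt_name, "LN": len(p.wt_seq)})
        refs.append({"SN": p.mut_name, "LN": len(p.mut_seq)})
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": refs}
    )
    rl = scenario.read_length
    mapq_hi, mapq_lo, frac_lo = scenario.mapq
    records: list[pysam.AlignedSegment] = []

    for entry in entries:
        pair = by_gene[entry.wt_contig]
        gene = pair.gene
        depth = scenario.depth_for(gene)
        f = scenario.fraction_for(gene)
        if depth == 0:
            continue
        from_mut = rng.random(depth) < f
        for i in range(depth):
            if from_mut[i]:
                contig, seq = pair.mut_name, pair.mut_seq
                lo_cov, hi_cov = _covered_interval(entry, mutant=True)
            else:
                contig, seq = pair.wt_name, pair.wt_seq
                lo_cov, hi_cov = _covered_interval(entry, mutant=False)
            start_min = max(1, hi_cov - rl + 1)
            start_max = min(lo_cov, len(seq) - rl + 1)
            if start_max < start_min:
                start_max = start_min  # degenerate: locus at the contig edge
            r1_start = int(rng.integers(start_min, start_max + 1))
            r2_start = min(r1_start + rl + scenario.insert_gap, len(seq) - rl + 1)
            name = f"{gene}:{entry.mutation.pos}:{i}"
            mapq = int(mapq_lo if rng.random() < frac_lo else mapq_hi)
            frag = _make_pair(header, name, contig, r1_start, r2_start, rl, seq,
                              mapq, scenario.error_rate, rng)
            records.extend(frag)
            if scenario.dup_rate and rng.random() < scenario.dup_rate:
                for r in frag:
                    dup = _clone(header, r)
                    dup.query_name = r.query_name + ":dup"
                    dup.is_duplicate = True
                    records.append(dup)
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.is_read2))
    return header, records


def _covered_interval(entry: MutationIndexEntry, mutant: bool) -> tuple[int, int]:
    """1-based closed interval the first mate must cover on its haplotype."""
    m = entry.mutation
    if m.mtype == "SNV":
        pos = entry.mut_pos if mutant else entry.wt_pos
        return pos, pos
    if m.mtype == "DEL":
        if mutant:
            return entry.mut_pos, entry.mut_pos
        return entry.wt_pos, entry.wt_pos + m.ref_len - 1
    # INS
    if mutant:
        return entry.mut_pos, entry.mut_pos + m.alt_len - 1
    return entry.wt_pos + 1, entry.wt_pos + 1


def _read_seq(seq: str, start: int, length: int, error_rate: float, rng) -> str:
    bases = seq[start - 1: start - 1 + length]
    if error_rate > 0:
        n_err = rng.binomial(length, error_rate)
        if n_err:
            arr = np.array(list(bases))
            pos = rng.choice(length, size=n_err, replace=False)
            for p in pos:
                arr[p] = rng.choice(_BASES[_BASES != arr[p]])
            bases = "".join(arr)
    return bases


def _make_pair(header, name, contig, r1_start, r2_start, rl, seq, mapq, error_rate, rng):
    tid = header.get_tid(contig)
    out = []
    for is_read2, start, mate_start in ((False, r1_start, r2_start), (True, r2_start, r1_start)):
        r = pysam.AlignedSegment(header)
        r.query_name = name
        r.reference_id = tid
        r.reference_start = start - 1
        r.mapping_quality = mapq
        r.cigarstring = f"{rl}M"
        r.query_sequence = _read_seq(seq, start, rl, error_rate, rng)
        r.next_reference_id = tid
        r.next_reference_start = mate_start - 1
        r.is_paired = True
        r.is_proper_pair = True
        r.is_read1 = not is_read2
        r.is_read2 = is_read2
        r.is_reverse = is_read2
        r.mate_is_reverse = not is_read2
        tlen = (r2_start + rl - 1) - r1_start + 1
        r.template_length = -tlen if is_read2 else tlen
        out.append(r)
    return out


def _clone(header, record: pysam.AlignedSegment) -> pysam.AlignedSegment:
    return pysam.AlignedSegment.fromstring(record.to_string(), header)


def expected_calls(
    scenario: SimScenario,
    config: ClassifierConfig = DEFAULT_CONFIG,
    mutations: Sequence[MutationRecord] | None = None,
) -> pd.DataFrame:
    """Analytic expectation of each mutation's group from (f, depth).

    A mutation whose planted fraction sits within three binomial
    standard errors of the V-ex/W-ex threshold (or whose depth sits on
    the discard-band edges) is labelled ``UNCERTAIN`` rather than
    forced into a group.
    """
    if mutations is None:
        _, _, mutations = simulate_reference(scenario)
    rows = []
    for m in mutations:
        depth = scenario.depth_for(m.gene)
        f = scenario.fraction_for(m.gene)
        rows.append({
            "gene": m.gene, "chrom": m.chrom, "pos": m.pos, "type": m.mtype,
            "fraction": f, "depth": depth,
            "expected_group": _expected_group(f, depth, config),
        })
    return pd.DataFrame(rows)


def _expected_group(f: float, depth: int, config: ClassifierConfig) -> str:
    # the first mate always covers the locus and the second sometimes does,
    # so the realised total lies in [depth, 2*depth]
    if depth == 0:
        return "N_EX"
    if 2 * depth < config.discard_min:
        return "N_EX"
    if config.discard_min <= depth and 2 * depth <= config.discard_max:
        return "DISCARDED"
    if depth > config.discard_max:
        se = (f * (1 - f) / depth) ** 0.5
        if abs(f - config.vex_min_maf) <= 3 * se or f == config.vex_min_maf:
            return "UNCERTAIN"
        return "V_EX" if f > config.vex_min_maf else "W_EX"
    return "UNCERTAIN"


# ---------------------------------------------------------------------------
# in-memory end-to-end convenience (used heavily by tests and validation)
# ---------------------------------------------------------------------------

def run_scenario(
    scenario: SimScenario,
    filter_config: FilterConfig | None = None,
    classifier_config: ClassifierConfig = DEFAULT_CONFIG,
    mark_internally: bool = False,
):
    """Simulate, build the reference, filter, count and classify in memory.

    Returns ``(profile, counts, entries, stats)``.
    """
    genome, models, mutations = simulate_reference(scenario)
    pairs, entries, _ = build_custom_reference(genome, models, mutations)
    header, records = simulate_alignments(pairs, entries, scenario)
    stats = FilterStats()
    kept = list(filter_alignments(records, filter_config, mark_internally=mark_internally, stats=stats))
    counts = count_sample(kept, entries, header=header)
    profile = build_profile(scenario.sample, mutations, counts, classifier_config)
    return profile, counts, entries, stats


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as out:
        for chrom in genome:
            out.write(f">{chrom}\n")
            out.write(textwrap.fill(genome[chrom], width) + "\n")


def write_gtf(models: Iterable[GeneModel], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for m in models:
            attrs = f'gene_id "{m.gene}"; gene_name "{m.gene}";'
            out.write(
                f"{m.chrom}\tallelex_sim\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )


def write_sam(
    header: pysam.AlignmentHeader,
    records: Iterable[pysam.AlignedSegment],
    path: Union[str, Path],
) -> None:
    mode = "wb" if str(path).endswith(".bam") else "wh"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in records:
            out.write(r)


def scenario_from_dict(data: Mapping) -> SimScenario:
    fields = {f.name for f in dataclasses.fields(SimScenario)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown scenario key(s): {', '.join(sorted(unknown))}")
    kwargs = dict(data)
    if "mapq" in kwargs and isinstance(kwargs["mapq"], (list, tuple)):
        kwargs["mapq"] = tuple(kwargs["mapq"])
    return SimScenario(**kwargs)
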