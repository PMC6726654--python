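"""Post-alignment filtering ahead of allele counting.

Three predicates, applied in order: drop PCR duplicates, keep uniquely
aligned reads (mapping quality at or above a cutoff, default 50, and no
secondary or unmapped records), and drop singletons (paired reads whose
mate is unmapped).  Unpaired reads pass the singleton step untouched, so
the step disables itself for single-end libraries.

Records are :class:`pysam.AlignedSegment`; all functions are lazy
generators that preserve the order of surviving records, so filtering a
coordinate-sorted stream yields a coordinate-sorted stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .errors import OrderingError


@dataclass
class FilterConfig:
    min_mapq: int = 50
    drop_duplicates: bool = True
    drop_singletons: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class FilterStats:
    """Per-stage drop counters filled in by the filter generators."""

    n_input: int = 0
    dropped_duplicate: int = 0
    dropped_mapq: int = 0
    dropped_singleton: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "dropped_duplicate": self.dropped_duplicate,
            "dropped_mapq_or_secondary": self.dropped_mapq,
            "dropped_singleton": self.dropped_singleton,
            "kept": self.n_kept,
        }


def remove_duplicates(
    records: Iterable[pysam.AlignedSegment],
    mark_internally: bool = False,
    stats: FilterStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Drop records carrying the duplicate flag.

    With ``mark_internally`` on, additionally treat records sharing
    (contig, pos, orientation, cigar, mate position) as duplicates and
    keep the first — a deterministic stand-in for an external duplicate
    marker when the input carries no duplicate flags.  Internal marking
    requires the stream to be coordinate-sorted.
    """
    last_locus: tuple[int, int] | None = None
    seen_keys: set = set()
    for r in records:
        if stats is not None:
            stats.n_input += 1
        if r.is_duplicate:
            if stats is not None:
                stats.dropped_duplicate += 1
            continue
        if mark_internally and not r.is_unmapped:
            locus = (r.reference_id, r.reference_start)
            if last_locus is not None and locus < last_locus:
                raise OrderingError(
                    "internal duplicate marking requires coordinate-sorted input "
                    f"(saw {locus} after {last_locus})"
                )
            if locus != last_locus:
                last_locus = locus
                seen_keys = set()
            key = (r.is_reverse, r.cigarstring, r.next_reference_start)
            if key in seen_keys:
                if stats is not None:
                    stats.dropped_duplicate += 1
                continue
            seen_keys.add(key)
        yield r


def filter_unique(
    records: Iterable[pysam.AlignedSegment],
    config: FilterConfig | None = None,
    stats: FilterStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Keep records with mapq >= min_mapq that are neither secondary nor unmapped."""
    config = config or FilterConfig()
    for r in records:
        if r.is_unmapped or r.is_secondary or r.mapping_quality < config.min_mapq:
            if stats is not None:
                stats.dropped_mapq += 1
            continue
        yield r


def remove_singletons(
    records: Iterable[pysam.AlignedSegment],
    stats: FilterStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Drop paired records whose mate is unmapped; unpaired records pass."""
    for r in records:
        if r.is_paired and r.mate_is_unmapped:
            if stats is not None:
                stats.dropped_singleton += 1
            continue
        yield r


def filter_alignments(
    records: Iterable[pysam.AlignedSegment],
    config: FilterConfig | None = None,
    mark_internally: bool = False,
    stats: FilterStats | None = None,
) -> Iterator[pysam.AlignedSegment]:
    """Compose the three filters: duplicates -> unique -> singletons."""
    config = config or FilterConfig()
    stream: Iterable[pysam.AlignedSegment] = records
    if config.drop_duplicates:
        stream = remove_duplicates(stream, mark_internally=mark_internally, stats=stats)
    elif stats is not None:
        stream = _count_input(stream, stats)
    stream = filter_unique(stream, config, stats=stats)
    if config.drop_singletons:
        stream = remove_singletons(stream, stats=stats)
    for r in stream:
        if stats is not None:
            stats.n_kept += 1
        yield r


def _count_input(records, stats: FilterStats):
    for r in records:
        stats.n_input += 1
        yield r


def filter_file(
    in_path: str,
    out_path: str,
    config: FilterConfig | None = None,
    mark_internally: bool = False,
) -> FilterStats:
    """Filter a SAM/BAM file to a SAM/BAM file, returning stage counts."""
    stats = FilterStats()
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        mode = "wb" if str(out_path).endswith(".bam") else "wh"
        with pysam.AlignmentFile(out_path, mode, header=src.header) as dst:
            for r in filter_alignments(src, config, mark_internally=mark_internally, stats=stats):
                dst.write(r)
    return stats
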