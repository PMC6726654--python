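"""Wild-type / mutant read counting against the dual-contig reference.

A read supports the allele of the contig it aligned to, so counting
reduces to pileup depth at the indexed positions:

* SNV — wild-type support is the depth at ``wt_pos`` on the wild-type
  contig, mutant support the depth at ``mut_pos`` on the mutant contig
  (the same base, remapped).
* deletion of length L — wild-type support is the *average* depth over
  the L deleted bases on the wild-type contig; mutant support is the
  depth at the first non-deleted base on the mutant contig.
* insertion of length L — mutant support is the average depth over the
  L inserted bases on the mutant contig; wild-type support is the depth
  at the first non-inserted base (the base after the anchor) on the
  wild-type contig.

Averaged depths stay fractional; the RNA mutant-allele frequency is
``mut / (wt + mut)`` and is undefined when no read covers either allele.

Depth at a position counts records whose CIGAR places an aligned
(match-consuming) base there: deletions and reference skips inside a
read contribute nothing at the positions they span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .errors import BoundsError, ReferenceMismatchError
from .genome_builder import MutationIndexEntry

logger = logging.getLogger(__name__)

_OP_MATCH = frozenset((0, 7, 8))  # M, =, X consume reference and query
_OP_REF_GAP = frozenset((2, 3))   # D, N consume reference only


def iter_match_blocks(record: pysam.AlignedSegment):
    """Yield 0-based half-open reference intervals covered by aligned bases."""
    pos = record.reference_start
    for op, length in record.cigartuples or ():
        if op in _OP_MATCH:
            yield pos, pos + length
            pos += length
        elif op in _OP_REF_GAP:
            pos += length


class ContigDepth:
    """Per-position aligned-base depth on one contig.

    Built incrementally from records; the depth vector is materialised
    lazily from interval endpoints, which keeps adding reads O(1) per
    CIGAR block.
    """

    def __init__(self, records: Iterable[pysam.AlignedSegment] = (), length: int | None = None):
        self.length = length
        self._starts: list[int] = []
        self._ends: list[int] = []
        self._depth: np.ndarray | None = None
        for r in records:
            self.add(r)

    def add(self, record: pysam.AlignedSegment) -> None:
        for start, end in iter_match_blocks(record):
            self._starts.append(start)
            self._ends.append(end)
        self._depth = None

    def _vector(self) -> np.ndarray:
        if self._depth is None:
            if not self._starts:
                self._depth = np.zeros(0, dtype=np.int64)
            else:
                # depth[i] = #(starts <= i) - #(ends <= i), by cumulative sum of deltas
                size = max(self._ends)
                starts = np.bincount(np.asarray(self._starts), minlength=size + 1)[: size + 1]
                ends = np.bincount(np.asarray(self._ends), minlength=size + 1)[: size + 1]
                self._depth = np.cumsum(starts - ends)[:size]
        return self._depth

    def at(self, position: int) -> int:
        """Depth at a 1-based position (0 beyond covered range)."""
        if position < 1:
            raise BoundsError(f"position must be >= 1, got {position}")
        if self.length is not None and position > self.length:
            raise BoundsError(f"position {position} beyond contig length {self.length}")
        vec = self._vector()
        idx = position - 1
        return int(vec[idx]) if idx < len(vec) else 0

    def mean(self, start: int, n: int) -> float:
        """Mean depth over ``n`` consecutive 1-based positions from ``start``."""
        return sum(self.at(start + i) for i in range(n)) / n


def depth_at(records, position: int) -> int:
    """Number of records whose CIGAR places an aligned base on ``position``."""
    if isinstance(records, ContigDepth):
        return records.at(position)
    return ContigDepth(records).at(position)


@dataclass(frozen=True)
class AlleleCounts:
    """Read support for the two alleles of one mutation."""

    wt_reads: float
    mut_reads: float

    def __post_init__(self) -> None:
        if self.wt_reads < 0 or self.mut_reads < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def total(self) -> float:
        return self.wt_reads + self.mut_reads

    @property
    def rna_maf(self) -> float | None:
        """RNA mutant-allele frequency; None when no read covers the locus."""
        if self.total == 0:
            return None
        return self.mut_reads / self.total


def count_alleles(wt_records, mut_records, entry: MutationIndexEntry) -> AlleleCounts:
    """Apply the per-type counting rule for one mutation.

    ``wt_records`` / ``mut_records`` are the filtered alignments on the
    wild-type and mutant contig (any iterable, or pre-built
    :class:`ContigDepth` objects).
    """
    wt = wt_records if isinstance(wt_records, ContigDepth) else ContigDepth(wt_records)
    mu = mut_records if isinstance(mut_records, ContigDepth) else ContigDepth(mut_records)
    m = entry.mutation
    if m.mtype == "SNV":
        w = float(wt.at(entry.wt_pos))
        v = float(mu.at(entry.mut_pos))
    elif m.mtype == "DEL":
        w = wt.mean(entry.wt_pos, m.ref_len)
        v = float(mu.at(entry.mut_pos))
    else:  # INS
        v = mu.mean(entry.mut_pos, m.alt_len)
        w = float(wt.at(entry.wt_pos + 1))
    return AlleleCounts(wt_reads=w, mut_reads=v)


COUNTS_COLUMNS = ("gene", "genomic_pos", "type", "wt_reads", "mut_reads", "total", "rna_maf")


def count_sample(
    alignments,
    entries: Sequence[MutationIndexEntry],
    header: pysam.AlignmentHeader | None = None,
    strict_base: bool = False,
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count both alleles for every index entry of one sample.

    ``alignments`` is a SAM/BAM path or an iterable of filtered
    :class:`pysam.AlignedSegment`.  Mutations whose contigs received no
    reads get zero counts (with a warning); if the alignment contigs
    share nothing at all with the index, a reference mismatch is raised.

    ``strict_base`` additionally requires the aligned read base at the
    counted position to match the contig base there, which needs the
    contig ``sequences``.
    """
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as handle:
            return count_sample(
                list(handle), entries, header=handle.header,
                strict_base=strict_base, sequences=sequences,
            )
    if strict_base and sequences is None:
        raise ValueError("strict_base counting requires contig sequences")

    records = list(alignments)
    lengths: dict[str, int] = {}
    if header is not None:
        lengths = {name: header.get_reference_length(name) for name in header.references}

    per_contig: dict[str, list[pysam.AlignedSegment]] = {}
    for r in records:
        if r.is_unmapped:
            continue
        per_contig.setdefault(r.reference_name, []).append(r)

    index_contigs = {e.wt_contig for e in entries} | {e.mut_contig for e in entries}
    known = set(lengths) | set(per_contig)
    if entries and known and not (index_contigs & known):
        raise ReferenceMismatchError(
            "no contig of the alignment file matches the mutation index; "
            "were the reads aligned to a different reference?"
        )

    depths: dict[str, ContigDepth] = {}

    def depth_for(contig: str) -> ContigDepth:
        if contig not in depths:
            depths[contig] = ContigDepth(per_contig.get(contig, ()), length=lengths.get(contig))
        return depths[contig]

    rows = []
    for e in entries:
        for contig in (e.wt_contig, e.mut_contig):
            if contig not in known and known:
                logger.warning("contig %s absent from alignments; zero counts", contig)
        if strict_base:
            counts = _count_alleles_strict(per_contig, e, sequences)
        else:
            counts = count_alleles(depth_for(e.wt_contig), depth_for(e.mut_contig), e)
        maf = counts.rna_maf
        rows.append({
            "gene": e.wt_contig, "genomic_pos": e.mutation.pos, "type": e.mutation.mtype,
            "wt_reads": counts.wt_reads, "mut_reads": counts.mut_reads,
            "total": counts.total, "rna_maf": math.nan if maf is None else maf,
        })
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def _query_index_at(record: pysam.AlignedSegment, position: int) -> int | None:
    """Query offset of the aligned base at a 1-based reference position."""
    target = position - 1
    ref = record.reference_start
    query = 0
    for op, length in record.cigartuples or ():
        if op in _OP_MATCH:
            if ref <= target < ref + length:
                return query + (target - ref)
            ref += length
            query += length
        elif op in _OP_REF_GAP:
            if ref <= target < ref + length:
                return None
            ref += length
        elif op in (1, 4):  # I, S consume query only
            query += length
    return None


def _strict_depth(records, position: int, base: str) -> int:
    n = 0
    for r in records:
        qi = _query_index_at(r, position)
        if qi is not None and r.query_sequence and r.query_sequence[qi] == base:
            n += 1
    return n


def _count_alleles_strict(per_contig, entry: MutationIndexEntry, sequences) -> AlleleCounts:
    m = entry.mutation
    wt_recs = per_contig.get(entry.wt_contig, ())
    mu_recs = per_contig.get(entry.mut_contig, ())
    wt_seq = sequences.get(entry.wt_contig, "")
    mu_seq = sequences.get(entry.mut_contig, "")

    def wt_base(pos: int) -> str:
        return wt_seq[pos - 1] if 0 < pos <= len(wt_seq) else "?"

    def mu_base(pos: int) -> str:
        return mu_seq[pos - 1] if 0 < pos <= len(mu_seq) else "?"

    if m.mtype == "SNV":
        w = float(_strict_depth(wt_recs, entry.wt_pos, wt_base(entry.wt_pos)))
        v = float(_strict_depth(mu_recs, entry.mut_pos, mu_base(entry.mut_pos)))
    elif m.mtype == "DEL":
        w = sum(
            _strict_depth(wt_recs, entry.wt_pos + i, wt_base(entry.wt_pos + i))
            for i in range(m.ref_len)
        ) / m.ref_len
        v = float(_strict_depth(mu_recs, entry.mut_pos, mu_base(entry.mut_pos)))
    else:
        v = sum(
            _strict_depth(mu_recs, entry.mut_pos + i, mu_base(entry.mut_pos + i))
            for i in range(m.alt_len)
        ) / m.alt_len
        w = float(_strict_depth(wt_recs, entry.wt_pos + 1, wt_base(entry.wt_pos + 1)))
    return AlleleCounts(wt_reads=w, mut_reads=v)


def write_counts(counts: pd.DataFrame, path: Union[str, Path]) -> None:
    counts.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_counts(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene": str})
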