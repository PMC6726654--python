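"""Tumor-specific dual-contig reference construction.

For every gene that carries somatic mutations in a sample, this module
emits a *pair* of contigs: the wild-type genomic sequence of the gene
(header ``>GENE``) and the same sequence with all of the sample's
mutations spliced in (header ``>GENE_Mut``).  RNA-seq reads aligned
against such a reference sort themselves onto the haplotype they support,
so allele assignment becomes a question of *which contig* a read landed
on rather than per-base mismatch inspection.  Restricting the reference
to mutated genes keeps it small and alignment fast.

Insertions and deletions change downstream coordinates, so mutations are
applied with a shifting algorithm that tracks the cumulative length
offset contributed by upstream indels.  The resulting coordinate map is
written as an *index* relating each mutation's genomic position to its
position on both contigs; the allele counter consumes this index.

Coordinate conventions (used consistently across the package):

* all positions are 1-based and fully closed;
* a deletion's ``pos`` is the first deleted base and ``ref`` spells the
  deleted bases (``alt`` is ``-``);
* an insertion's ``pos`` is the base immediately 5' of the inserted
  sequence (``ref`` is ``-``); on the mutant contig the recorded
  position is the first *inserted* base.

Gene sequences are the full genomic span of the GTF ``gene`` feature,
introns included, always on the reference (+) strand.  Strand is
recorded but sequences are never reverse-complemented: aligners handle
both orientations and keeping one orientation makes the coordinate map
affine per gene.
"""

from __future__ import annotations

import re
import textwrap
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gffutils
import pandas as pd

from .errors import (
    BoundsError,
    ChromosomeNotFoundError,
    ConfigError,
    MutationFileError,
    OverlapError,
    RefMismatchError,
)

MUTATION_TYPES = ("SNV", "INS", "DEL")
_DNA_RE = re.compile(r"^[ACGT]+$")

#: columns of the native tab-separated mutation dialect
TSV_COLUMNS = ("sample", "gene", "chrom", "pos", "ref", "alt", "type")

#: MAF (Mutation Annotation Format) column mapping onto the native dialect
MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "type": "Variant_Type",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant owned by a sample and a gene.

    ``dna_af`` is the DNA (exome) variant allele frequency when known; it
    is carried through to the expression profile so DNA and RNA allele
    frequencies can be compared side by side.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mtype: str
    dna_af: float | None = None

    def __post_init__(self) -> None:
        if self.mtype not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mtype!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.mtype == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNV requires single-base ref and alt")
            if self.ref == self.alt:
                raise ValueError("SNV ref and alt must differ")
            _require_dna(self.ref), _require_dna(self.alt)
        elif self.mtype == "DEL":
            if self.alt != "-":
                raise ValueError("DEL requires alt == '-'")
            _require_dna(self.ref)
        else:  # INS
            if self.ref != "-":
                raise ValueError("INS requires ref == '-'")
            _require_dna(self.alt)
        if self.dna_af is not None and not 0.0 <= self.dna_af <= 1.0:
            raise ValueError(f"dna_af outside [0, 1]: {self.dna_af}")

    @property
    def ref_len(self) -> int:
        return 0 if self.ref == "-" else len(self.ref)

    @property
    def alt_len(self) -> int:
        return 0 if self.alt == "-" else len(self.alt)

    @property
    def end(self) -> int:
        """Last genomic base occupied by the edit (== pos for SNV/INS)."""
        return self.pos + max(self.ref_len - 1, 0)


def _require_dna(allele: str) -> None:
    if not _DNA_RE.match(allele):
        raise ValueError(f"allele {allele!r} contains non-ACGT characters")


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic footprint from the annotation (1-based, closed)."""

    gene: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be + or -")

    @property
    def symbol(self) -> str:
        """Base gene symbol with any '#k' disambiguation suffix removed."""
        return self.gene.split("#", 1)[0]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenePair:
    """Wild-type and mutant contig of one mutated gene."""

    gene: str
    wt_seq: str
    mut_seq: str
    origin: GeneModel

    @property
    def wt_name(self) -> str:
        return self.gene

    @property
    def mut_name(self) -> str:
        return self.gene + "_Mut"

    @property
    def wt_header(self) -> str:
        return ">" + self.wt_name

    @property
    def mut_header(self) -> str:
        return ">" + self.mut_name


@dataclass(frozen=True)
class MutationIndexEntry:
    """Remapped coordinates of one mutation on both contigs.

    ``shift`` is the cumulative length offset contributed by indels
    strictly upstream of this mutation, i.e. the offset already in force
    when the mutation itself is applied.
    """

    mutation: MutationRecord
    wt_contig: str
    wt_pos: int
    mut_contig: str
    mut_pos: int
    shift: int


# ---------------------------------------------------------------------------
# mutation table parsing
# ---------------------------------------------------------------------------

def parse_mutation_file(path: Union[str, Path], dialect: str = "tsv") -> list[MutationRecord]:
    """Read a mutation table and return validated records.

    ``dialect`` is ``"tsv"`` for the native format (columns
    ``sample gene chrom pos ref alt type [dna_af]``) or ``"maf"`` for
    MAF-compatible tables (``Variant_Type`` values ``SNP/INS/DEL``; a
    ``dna_af`` is derived from ``t_alt_count``/``t_depth`` when present).

    Rows violating the per-type allele constraints are rejected together
    with their row numbers.  Records come back grouped and sorted by
    (sample, gene, pos).
    """
    if dialect not in ("tsv", "maf"):
        raise ConfigError(f"unknown mutation dialect {dialect!r}")
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise MutationFileError(f"{path}: empty file, expected a header row")

    if dialect == "maf":
        missing = [c for c in MAF_COLUMNS.values() if c not in table.columns]
        if missing:
            raise MutationFileError(f"{path}: missing MAF column(s) {', '.join(missing)}")
        frame = table.rename(columns={v: k for k, v in MAF_COLUMNS.items()})
        if "t_alt_count" in table.columns and "t_depth" in table.columns:
            alt_n = pd.to_numeric(table["t_alt_count"], errors="coerce")
            depth = pd.to_numeric(table["t_depth"], errors="coerce")
            frame["dna_af"] = (alt_n / depth).where(depth > 0)
    else:
        missing = [c for c in TSV_COLUMNS if c not in table.columns]
        if missing:
            raise MutationFileError(f"{path}: missing column(s) {', '.join(missing)}")
        frame = table

    records: list[MutationRecord] = []
    problems: list[str] = []
    for i, row in frame.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise MutationFileError(f"{path}: {len(problems)} invalid row(s)\n" + "\n".join(problems))
    records.sort(key=lambda m: (m.sample_id, m.gene, m.pos))
    return records


def _row_to_record(row: pd.Series) -> MutationRecord:
    mtype = str(row["type"]).strip().upper()
    if mtype == "SNP":
        mtype = "SNV"
    ref = str(row["ref"]).strip().upper()
    alt = str(row["alt"]).strip().upper()
    if ref == "-" and alt == "-":
        raise ValueError("ref and alt are both '-'")
    dna_af = None
    raw_af = row.get("dna_af")
    if raw_af is not None and str(raw_af).strip() not in ("", "nan", "NA", "."):
        dna_af = float(raw_af)
    return MutationRecord(
        sample_id=str(row["sample"]).strip(),
        gene=str(row["gene"]).strip(),
        chrom=str(row["chrom"]).strip(),
        pos=int(row["pos"]),
        ref=ref,
        alt=alt,
        mtype=mtype,
        dna_af=dna_af,
    )


def write_mutation_tsv(mutations: Iterable[MutationRecord], path: Union[str, Path]) -> None:
    """Write records in the native tab-separated dialect."""
    rows = [
        {
            "sample": m.sample_id, "gene": m.gene, "chrom": m.chrom, "pos": m.pos,
            "ref": m.ref, "alt": m.alt, "type": m.mtype,
            "dna_af": "" if m.dna_af is None else m.dna_af,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=list(TSV_COLUMNS) + ["dna_af"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_gene_sequence(genome, model: GeneModel) -> str:
    """Return the genomic span [start, end] of ``model``, uppercased.

    ``genome`` may be a :class:`pyfaidx.Fasta` handle or any mapping of
    chromosome name to sequence string.  The span is always taken on the
    reference (+) strand.
    """
    try:
        chrom = genome[model.chrom]
    except KeyError:
        raise ChromosomeNotFoundError(f"chromosome {model.chrom!r} not in reference genome")
    if model.end > len(chrom):
        raise BoundsError(
            f"gene {model.gene}: span end {model.end} exceeds {model.chrom} length {len(chrom)}"
        )
    sliced = chrom[model.start - 1: model.end]
    seq = sliced.seq if hasattr(sliced, "seq") else str(sliced)
    return seq.upper()


# ---------------------------------------------------------------------------
# the shifting algorithm
# ---------------------------------------------------------------------------

def _occupied_span(m: MutationRecord) -> tuple[int, int]:
    # INS occupies only its anchor base; SNV its base; DEL its deleted range.
    return m.pos, m.end


def _check_overlap(muts: Sequence[MutationRecord], gene: GeneModel) -> None:
    prev_start = prev_end = None
    prev_type = None
    ins_anchors: set[int] = set()
    for m in muts:
        s, e = _occupied_span(m)
        if m.mtype == "INS":
            if m.pos in ins_anchors:
                raise OverlapError(f"gene {gene.gene}: two insertions anchored at {m.chrom}:{m.pos}")
            ins_anchors.add(m.pos)
        if prev_end is not None and s <= prev_end:
            # the one legal co-location: substitute a base, then insert after it
            same_base = s == prev_end == prev_start
            if not (same_base and {prev_type, m.mtype} == {"SNV", "INS"}):
                raise OverlapError(
                    f"gene {gene.gene}: mutations at {m.chrom}:{m.pos} overlap an "
                    f"upstream edit ending at {prev_end}"
                )
        if prev_end is None or e > prev_end:
            prev_start, prev_end, prev_type = s, e, m.mtype


def apply_mutations(
    wt_seq: str,
    mutations: Iterable[MutationRecord],
    gene: GeneModel,
    check_ref: bool = True,
) -> tuple[str, list[MutationIndexEntry]]:
    """Splice all of a gene's mutations into its wild-type sequence.

    Mutations are applied left to right with a running ``shift`` equal to
    the net length change of upstream indels, so a single pass produces
    both the mutant sequence and the coordinate index.  The result is
    independent of input order (mutations are sorted internally).

    With ``check_ref`` on (the default), each SNV/DEL reference allele is
    verified against ``wt_seq`` — this catches 0/1-based off-by-one
    errors in upstream mutation calls early.
    """
    # SNV sorts before INS at the same anchor so the substituted base is
    # emitted before the inserted bases
    muts = sorted(mutations, key=lambda m: (m.pos, 1 if m.mtype == "INS" else 0))
    for m in muts:
        if m.pos < gene.start or m.end > gene.end:
            raise BoundsError(
                f"gene {gene.gene}: mutation at {m.chrom}:{m.pos} outside span "
                f"[{gene.start}, {gene.end}]"
            )
    _check_overlap(muts, gene)

    pieces: list[str] = []
    entries: list[MutationIndexEntry] = []
    cursor = 1  # next wild-type position (1-based) not yet emitted
    shift = 0
    wt_name = gene.gene
    mut_name = gene.gene + "_Mut"
    for m in muts:
        p = m.pos - gene.start + 1  # position on the wild-type contig
        if m.mtype == "SNV":
            if check_ref and wt_seq[p - 1] != m.ref:
                raise RefMismatchError(
                    f"gene {gene.gene} pos {m.pos}: ref {m.ref!r} != sequence "
                    f"{wt_seq[p - 1]!r}"
                )
            pieces.append(wt_seq[cursor - 1: p - 1])
            pieces.append(m.alt)
            entries.append(MutationIndexEntry(m, wt_name, p, mut_name, p + shift, shift))
            cursor = p + 1
        elif m.mtype == "DEL":
            length = m.ref_len
            if check_ref and wt_seq[p - 1: p - 1 + length] != m.ref:
                raise RefMismatchError(
                    f"gene {gene.gene} pos {m.pos}: ref {m.ref!r} != sequence "
                    f"{wt_seq[p - 1: p - 1 + length]!r}"
                )
            pieces.append(wt_seq[cursor - 1: p - 1])
            # mut_pos = first non-deleted base on the mutant contig
            entries.append(MutationIndexEntry(m, wt_name, p, mut_name, p + shift, shift))
            cursor = p + length
            shift -= length
        else:  # INS: anchor base p stays, alt goes right after it
            pieces.append(wt_seq[cursor - 1: p])
            entries.append(MutationIndexEntry(m, wt_name, p, mut_name, p + shift + 1, shift))
            pieces.append(m.alt)
            cursor = p + 1
            shift += m.alt_len
    pieces.append(wt_seq[cursor - 1:])
    return "".join(pieces), entries


def verify_index_entry(pair: GenePair, entry: MutationIndexEntry) -> bool:
    """Check that allele lookup on both contigs reproduces ref and alt."""
    m = entry.mutation
    wt, mu = pair.wt_seq, pair.mut_seq
    wp, mp = entry.wt_pos, entry.mut_pos
    if m.mtype == "SNV":
        return wt[wp - 1] == m.ref and mu[mp - 1] == m.alt
    if m.mtype == "DEL":
        length = m.ref_len
        if wt[wp - 1: wp - 1 + length] != m.ref:
            return False
        # first non-deleted base mirrors the wild-type base after the deletion
        after = wp - 1 + length
        if after < len(wt):
            return mp <= len(mu) and mu[mp - 1] == wt[after]
        return True
    # INS
    length = m.alt_len
    return mu[mp - 1: mp - 1 + length] == m.alt and wt[wp - 1] != ""


# ---------------------------------------------------------------------------
# annotation loading & reference assembly
# ---------------------------------------------------------------------------

def load_gene_models(gtf_path: Union[str, Path]) -> list[GeneModel]:
    """Load ``gene`` features from a GTF, disambiguating duplicate symbols.

    The second and later occurrences of a repeated ``gene_name`` get a
    ``#k`` ordinal suffix so that contig headers map one-to-one onto
    gene models.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    names: list[str] = []
    raw: list[tuple[str, str, str, int, int]] = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        name = (attrs.get("gene_name") or attrs.get("gene_id") or [feat.id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        names.append(name)
        raw.append((name, feat.seqid, strand, feat.start, feat.end))

    seen: dict[str, int] = defaultdict(int)
    total = defaultdict(int)
    for n in names:
        total[n] += 1
    models = []
    for name, chrom, strand, start, end in raw:
        seen[name] += 1
        label = name if seen[name] == 1 else f"{name}#{seen[name]}"
        models.append(GeneModel(gene=label, chrom=chrom, strand=strand, start=start, end=end))
    return models


def build_custom_reference(
    genome,
    annotation,
    mutations: Sequence[MutationRecord],
    check_ref: bool = True,
    sample_id: str | None = None,
) -> tuple[list[GenePair], list[MutationIndexEntry], list[tuple[MutationRecord, str]]]:
    """Assemble the dual-contig reference for one sample.

    ``annotation`` may be a GTF path or a pre-loaded list of
    :class:`GeneModel`.  Mutations naming a gene absent from the
    annotation (or whose coordinates fall outside every candidate model)
    are routed to the returned ``skipped`` list with a reason rather than
    aborting the build.  The output FASTA contains *only* mutated genes.
    """
    if isinstance(annotation, (str, Path)):
        models = load_gene_models(annotation)
    else:
        models = list(annotation)

    muts = list(mutations)
    if sample_id is not None:
        muts = [m for m in muts if m.sample_id == sample_id]
    sample_ids = {m.sample_id for m in muts}
    if len(sample_ids) > 1:
        raise ConfigError(
            "reference construction is per sample; pass sample_id to select one of "
            + ", ".join(sorted(sample_ids))
        )

    by_symbol: dict[str, list[GeneModel]] = defaultdict(list)
    for model in models:
        by_symbol[model.symbol].append(model)

    assigned: dict[str, list[MutationRecord]] = defaultdict(list)
    skipped: list[tuple[MutationRecord, str]] = []
    for m in muts:
        candidates = by_symbol.get(m.gene, [])
        if not candidates:
            skipped.append((m, "no gene model"))
            continue
        containing = [
            c for c in candidates
            if c.chrom == m.chrom and c.start <= m.pos and m.end <= c.end
        ]
        if len(containing) == 1:
            assigned[containing[0].gene].append(m)
        elif not containing:
            skipped.append((m, "coordinates outside gene model span"))
        else:
            skipped.append((m, "ambiguous gene symbol"))

    pairs: list[GenePair] = []
    entries: list[MutationIndexEntry] = []
    for model in models:  # annotation order keeps output deterministic
        gene_muts = assigned.get(model.gene)
        if not gene_muts:
            continue
        wt_seq = extract_gene_sequence(genome, model)
        mut_seq, gene_entries = apply_mutations(wt_seq, gene_muts, model, check_ref=check_ref)
        pairs.append(GenePair(gene=model.gene, wt_seq=wt_seq, mut_seq=mut_seq, origin=model))
        entries.extend(gene_entries)
    return pairs, entries, skipped


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

INDEX_COLUMNS = (
    "gene", "chrom", "genomic_pos", "ref", "alt", "type",
    "wt_contig", "wt_pos", "mut_contig", "mut_pos", "shift",
)


def write_reference_fasta(pairs: Iterable[GenePair], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as out:
        for pair in pairs:
            for header, seq in ((pair.wt_header, pair.wt_seq), (pair.mut_header, pair.mut_seq)):
                out.write(header + "\n")
                out.write(textwrap.fill(seq, width) + "\n")


def write_index(entries: Iterable[MutationIndexEntry], path: Union[str, Path]) -> None:
    rows = [
        {
            "gene": e.wt_contig, "chrom": e.mutation.chrom, "genomic_pos": e.mutation.pos,
            "ref": e.mutation.ref, "alt": e.mutation.alt, "type": e.mutation.mtype,
            "wt_contig": e.wt_contig, "wt_pos": e.wt_pos,
            "mut_contig": e.mut_contig, "mut_pos": e.mut_pos, "shift": e.shift,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(path, sep="\t", index=False)


def read_index(path: Union[str, Path], sample_id: str = "") -> list[MutationIndexEntry]:
    """Read an index TSV back into entries.

    The index file does not carry sample identity or DNA allele
    frequency; ``sample_id`` stamps the reconstructed mutation records.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    entries = []
    for _, row in table.iterrows():
        m = MutationRecord(
            sample_id=sample_id,
            gene=str(row["gene"]).split("#", 1)[0],
            chrom=str(row["chrom"]),
            pos=int(row["genomic_pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            mtype=str(row["type"]),
        )
        entries.append(MutationIndexEntry(
            mutation=m,
            wt_contig=str(row["wt_contig"]), wt_pos=int(row["wt_pos"]),
            mut_contig=str(row["mut_contig"]), mut_pos=int(row["mut_pos"]),
            shift=int(row["shift"]),
        ))
    return entries


def write_skipped(skipped: Iterable[tuple[MutationRecord, str]], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample": m.sample_id, "gene": m.gene, "chrom": m.chrom, "pos": m.pos,
            "ref": m.ref, "alt": m.alt, "type": m.mtype, "reason": reason,
        }
        for m, reason in skipped
    ]
    cols = ["sample", "gene", "chrom", "pos", "ref", "alt", "type", "reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
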