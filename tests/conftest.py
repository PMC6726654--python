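"""Shared fixtures: in-memory alignment records and tiny on-disk references."""

import pysam
import pytest

from allelex.genome_builder import GeneModel, MutationRecord


def _query_length(cigar: str) -> int:
    n, total = "", 0
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if ch in "MIS=X":
                total += int(n)
            n = ""
    return total


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "tig", "LN": 10000}, {"SN": "tig_Mut", "LN": 10000}],
    })


@pytest.fixture
def make_read(sam_header):
    """Factory for alignment records with sensible defaults."""

    counter = [0]

    def _make(
        pos=1,
        cigar="10M",
        contig="tig",
        mapq=60,
        name=None,
        duplicate=False,
        mate_unmapped=False,
        paired=True,
        secondary=False,
        unmapped=False,
        reverse=False,
        mate_pos=None,
    ):
        counter[0] += 1
        r = pysam.AlignedSegment(sam_header)
        r.query_name = name or f"read{counter[0]}"
        r.mapping_quality = mapq
        r.is_paired = paired
        r.is_duplicate = duplicate
        r.is_secondary = secondary
        r.is_reverse = reverse
        if unmapped:
            r.is_unmapped = True
        else:
            r.reference_id = sam_header.get_tid(contig)
            r.reference_start = pos - 1  # 1-based in tests, 0-based in pysam
            r.cigarstring = cigar
            r.query_sequence = "A" * _query_length(cigar)
        if paired:
            r.mate_is_unmapped = mate_unmapped
            if mate_pos is not None:
                r.next_reference_id = r.reference_id
                r.next_reference_start = mate_pos - 1
        return r

    return _make


@pytest.fixture
def toy_gene():
    return GeneModel(gene="KRAS", chrom="chr12", strand="+", start=101, end=160)


@pytest.fixture
def toy_reference(tmp_path):
    """A 2-chromosome FASTA + GTF with two genes, written to disk."""
    import random

    rng = random.Random(42)
    chroms = {
        "chr1": "".join(rng.choice("ACGT") for _ in range(400)),
        "chr2": "".join(rng.choice("ACGT") for _ in range(400)),
    }
    fasta = tmp_path / "ref.fa"
    with open(fasta, "w") as out:
        for name, seq in chroms.items():
            out.write(f">{name}\n{seq}\n")
    gtf = tmp_path / "ann.gtf"
    with open(gtf, "w") as out:
        out.write('chr1\ttest\tgene\t51\t250\t.\t+\t.\tgene_id "GA"; gene_name "GA";\n')
        out.write('chr2\ttest\tgene\t101\t300\t.\t-\t.\tgene_id "GB"; gene_name "GB";\n')
    return {"fasta": fasta, "gtf": gtf, "chroms": chroms}


def make_mutation(sample="S1", gene="GA", chrom="chr1", pos=100, ref="A", alt="C",
                  mtype="SNV", dna_af=None):
    return MutationRecord(sample_id=sample, gene=gene, chrom=chrom, pos=pos,
                         ref=ref, alt=alt, mtype=mtype, dna_af=dna_af)
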