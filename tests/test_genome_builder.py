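"""Reference construction: parsing, extraction, the shifting algorithm."""

import random

import pytest

from allelex.errors import (
    BoundsError,
    ChromosomeNotFoundError,
    MutationFileError,
    OverlapError,
    RefMismatchError,
)
from allelex.genome_builder import (
    GeneModel,
    MutationRecord,
    apply_mutations,
    build_custom_reference,
    extract_gene_sequence,
    load_gene_models,
    parse_mutation_file,
    read_index,
    verify_index_entry,
    write_index,
    GenePair,
)

from conftest import make_mutation


# ---------------------------------------------------------------------------
# independent oracle: apply edits right-to-left, no shift bookkeeping needed
# ---------------------------------------------------------------------------

def splice_oracle(wt, mutations, gene_start=1):
    s = wt
    for m in sorted(mutations, key=lambda m: (m.pos, 0 if m.mtype == "INS" else 1), reverse=True):
        p = m.pos - gene_start + 1
        if m.mtype == "SNV":
            s = s[: p - 1] + m.alt + s[p:]
        elif m.mtype == "DEL":
            s = s[: p - 1] + s[p - 1 + len(m.ref):]
        else:
            s = s[:p] + m.alt + s[p:]
    return s


def random_mutations(rng, seq, gene_start, max_n=10, sample="S", gene="G"):
    """Non-overlapping random mutations over a wild-type sequence."""
    n = rng.randint(0, max_n)
    taken = []
    muts = []
    tries = 0
    while len(muts) < n and tries < 500:
        tries += 1
        mtype = rng.choice(["SNV", "INS", "DEL"])
        length = 1 if mtype == "SNV" else rng.randint(1, 6)
        lo = 2 if mtype == "INS" else 1
        p = rng.randint(lo, len(seq) - length)
        span = (p - 7, p + length + 7)  # generous separation: no overlaps by construction
        if any(not (span[1] < s or e < span[0]) for s, e in taken):
            continue
        taken.append((p, p + length))
        pos = gene_start + p - 1
        if mtype == "SNV":
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
        elif mtype == "DEL":
            ref = seq[p - 1: p - 1 + length]
            alt = "-"
        else:
            ref = "-"
            alt = "".join(rng.choice("ACGT") for _ in range(length))
        muts.append(MutationRecord(sample, gene, "chr1", pos, ref, alt, mtype))
    return muts


# ---------------------------------------------------------------------------
# mutation table parsing
# ---------------------------------------------------------------------------

class TestParseMutationFile:
    def test_tsv_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tgene\tchrom\tpos\tref\talt\ttype\tdna_af\n"
            "S1\tKRAS\tchr12\t25398284\tC\tA\tSNV\t0.48\n"
        )
        (rec,) = parse_mutation_file(p)
        assert rec.gene == "KRAS" and rec.mtype == "SNV"
        assert rec.pos == 25398284 and rec.dna_af == pytest.approx(0.48)

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tgene\tchrom\tpos\tref\talt\ttype\n")
        assert parse_mutation_file(p) == []

    def test_maf_deletion_row(self, tmp_path):
        p = tmp_path / "m.maf"
        cols = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type"]
        p.write_text("\t".join(cols) + "\nS1\tTP53\tchr17\t7578200\tAG\t-\tDEL\n")
        (rec,) = parse_mutation_file(p, dialect="maf")
        assert rec.mtype == "DEL" and rec.ref == "AG" and rec.alt == "-"

    def test_maf_snp_maps_to_snv(self, tmp_path):
        p = tmp_path / "m.maf"
        cols = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type", "t_alt_count", "t_depth"]
        p.write_text("\t".join(cols) + "\nS1\tKRAS\tchr12\t25398284\tC\tA\tSNP\t30\t100\n")
        (rec,) = parse_mutation_file(p, dialect="maf")
        assert rec.mtype == "SNV" and rec.dna_af == pytest.approx(0.30)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tgene\tchrom\tpos\tref\talt\nS1\tG\tc\t1\tA\tC\n")
        with pytest.raises(MutationFileError, match="type"):
            parse_mutation_file(p)

    def test_bad_rows_reported_with_numbers(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tgene\tchrom\tpos\tref\talt\ttype\n"
            "S1\tG\tc\t5\tA\tC\tSNV\n"
            "S1\tG\tc\t9\t-\t-\tDEL\n"      # both dashes
            "S1\tG\tc\t12\tAN\t-\tDEL\n"     # non-DNA character
        )
        with pytest.raises(MutationFileError) as err:
            parse_mutation_file(p)
        assert "row 3" in str(err.value) and "row 4" in str(err.value)

    def test_records_sorted_by_sample_gene_pos(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tgene\tchrom\tpos\tref\talt\ttype\n"
            "S2\tB\tc\t5\tA\tC\tSNV\n"
            "S1\tB\tc\t9\tA\tC\tSNV\n"
            "S1\tA\tc\t50\tA\tC\tSNV\n"
            "S1\tB\tc\t2\tA\tC\tSNV\n"
        )
        recs = parse_mutation_file(p)
        assert [(r.sample_id, r.gene, r.pos) for r in recs] == [
            ("S1", "A", 50), ("S1", "B", 2), ("S1", "B", 9), ("S2", "B", 5)]


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

class TestExtractGeneSequence:
    def test_slice_and_boundary(self):
        genome = {"c": "ACGTACGTAC" * 10}
        model = GeneModel("G", "c", "+", 11, 20)
        assert extract_gene_sequence(genome, model) == genome["c"][10:20]
        single = GeneModel("G", "c", "+", 1, 1)
        assert extract_gene_sequence(genome, single) == "A"

    def test_random_span_equals_string_slice(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(5000))
        genome = {"c": seq}
        for _ in range(20):
            start = rng.randint(1, 4000)
            end = rng.randint(start, 5000)
            model = GeneModel("G", "c", "+", start, end)
            assert extract_gene_sequence(genome, model) == seq[start - 1: end]

    def test_lowercase_is_uppercased(self):
        genome = {"c": "acgtacgt"}
        assert extract_gene_sequence(genome, GeneModel("G", "c", "+", 1, 4)) == "ACGT"

    def test_errors(self):
        genome = {"c": "ACGT"}
        with pytest.raises(ChromosomeNotFoundError):
            extract_gene_sequence(genome, GeneModel("G", "nope", "+", 1, 2))
        with pytest.raises(BoundsError):
            extract_gene_sequence(genome, GeneModel("G", "c", "+", 1, 5))


# ---------------------------------------------------------------------------
# shifting algorithm
# ---------------------------------------------------------------------------

class TestApplyMutations:
    GENE = GeneModel("G", "c", "+", 1, 8)

    def test_mixed_edits_with_shift(self):
        muts = [
            MutationRecord("S", "G", "c", 2, "C", "G", "SNV"),
            MutationRecord("S", "G", "c", 4, "-", "TT", "INS"),
            MutationRecord("S", "G", "c", 7, "G", "A", "SNV"),
        ]
        mut_seq, entries = apply_mutations("ACGTACGT", muts, self.GENE)
        assert mut_seq == "AGGTTTACAT"
        assert [(e.wt_pos, e.mut_pos, e.shift) for e in entries] == [(2, 2, 0), (4, 5, 0), (7, 9, 2)]

    def test_empty_mutation_list_is_identity(self):
        mut_seq, entries = apply_mutations("ACGTACGT", [], self.GENE)
        assert mut_seq == "ACGTACGT" and entries == []

    def test_single_deletion(self):
        gene = GeneModel("G", "c", "+", 1, 5)
        mut_seq, entries = apply_mutations(
            "ACGTA", [MutationRecord("S", "G", "c", 3, "GT", "-", "DEL")], gene)
        assert mut_seq == "ACA"
        (e,) = entries
        assert (e.wt_pos, e.mut_pos, e.shift) == (3, 3, 0)

    def test_order_independence(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        gene = GeneModel("G", "c", "+", 1, 300)
        muts = random_mutations(rng, seq, 1, max_n=8)
        ref_seq, ref_entries = apply_mutations(seq, muts, gene)
        for _ in range(5):
            shuffled = muts[:]
            rng.shuffle(shuffled)
            out_seq, out_entries = apply_mutations(seq, shuffled, gene)
            assert out_seq == ref_seq and out_entries == ref_entries

    def test_ref_mismatch_names_gene_and_pos(self):
        with pytest.raises(RefMismatchError, match="G.*pos 2"):
            apply_mutations("ACGT", [MutationRecord("S", "G", "c", 2, "T", "A", "SNV")],
                            GeneModel("G", "c", "+", 1, 4))

    def test_ref_check_can_be_disabled(self):
        mut_seq, _ = apply_mutations(
            "ACGT", [MutationRecord("S", "G", "c", 2, "T", "A", "SNV")],
            GeneModel("G", "c", "+", 1, 4), check_ref=False)
        assert mut_seq == "AAGT"

    def test_out_of_span_is_bounds_error(self):
        with pytest.raises(BoundsError):
            apply_mutations("ACGT", [MutationRecord("S", "G", "c", 9, "A", "C", "SNV")],
                            GeneModel("G", "c", "+", 1, 4))

    @pytest.mark.parametrize("second", [
        MutationRecord("S", "G", "c", 3, "G", "A", "SNV"),    # SNV inside DEL
        MutationRecord("S", "G", "c", 4, "-", "AA", "INS"),   # INS at DEL boundary base
        MutationRecord("S", "G", "c", 3, "TA", "-", "DEL"),   # DEL over DEL
    ])
    def test_overlap_with_deletion_rejected(self, second):
        dele = MutationRecord("S", "G", "c", 3, "GT", "-", "DEL")
        gene = GeneModel("G", "c", "+", 1, 8)
        with pytest.raises(OverlapError):
            apply_mutations("ACGTACGT", [dele, second], gene, check_ref=False)

    def test_same_position_snvs_rejected(self):
        gene = GeneModel("G", "c", "+", 1, 8)
        muts = [MutationRecord("S", "G", "c", 2, "C", "G", "SNV"),
                MutationRecord("S", "G", "c", 2, "C", "T", "SNV")]
        with pytest.raises(OverlapError):
            apply_mutations("ACGTACGT", muts, gene)

    def test_length_conservation_random(self):
        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(100, 600)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            gene = GeneModel("G", "c", "+", 1, n)
            muts = random_mutations(rng, seq, 1)
            mut_seq, _ = apply_mutations(seq, muts, gene)
            delta = sum(len(m.alt) for m in muts if m.mtype == "INS") - sum(
                len(m.ref) for m in muts if m.mtype == "DEL")
            assert len(mut_seq) - len(seq) == delta

    def test_matches_splice_oracle_and_roundtrips(self):
        rng = random.Random(99)
        for _ in range(60):
            n = rng.randint(200, 1500)
            start = rng.randint(1, 10000)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            gene = GeneModel("G", "c", "+", start, start + n - 1)
            muts = random_mutations(rng, seq, start)
            mut_seq, entries = apply_mutations(seq, muts, gene)
            assert mut_seq == splice_oracle(seq, muts, start)
            pair = GenePair(gene="G", wt_seq=seq, mut_seq=mut_seq, origin=gene)
            assert all(verify_index_entry(pair, e) for e in entries)


# ---------------------------------------------------------------------------
# whole-reference assembly
# ---------------------------------------------------------------------------

class TestBuildCustomReference:
    def _setup(self, toy_reference):
        chroms = toy_reference["chroms"]
        models = load_gene_models(toy_reference["gtf"])
        return chroms, models

    def test_two_fasta_entries_per_gene(self, toy_reference):
        chroms, models = self._setup(toy_reference)
        def snv(gene, chrom, pos):
            ref = chroms[chrom][pos - 1]
            return make_mutation(gene=gene, chrom=chrom, pos=pos, ref=ref,
                                 alt="A" if ref != "A" else "C")

        muts = [snv("GA", "chr1", 100), snv("GA", "chr1", 150), snv("GB", "chr2", 200)]
        pairs, entries, skipped = build_custom_reference(chroms, models, muts)
        assert len(pairs) == 2 and len(entries) == 3 and not skipped
        names = [n for p in pairs for n in (p.wt_name, p.mut_name)]
        assert names == ["GA", "GA_Mut", "GB", "GB_Mut"]

    def test_unknown_gene_skipped_with_reason(self, toy_reference):
        chroms, models = self._setup(toy_reference)
        muts = [make_mutation(gene="NOPE", pos=100, ref="A", alt="C")]
        pairs, entries, skipped = build_custom_reference(chroms, models, muts)
        assert pairs == [] and entries == []
        ((skipped_mut, reason),) = skipped
        assert skipped_mut.gene == "NOPE" and reason == "no gene model"

    def test_out_of_span_mutation_skipped(self, toy_reference):
        chroms, models = self._setup(toy_reference)
        muts = [make_mutation(gene="GA", pos=390, ref=chroms["chr1"][389], alt="A"
                              if chroms["chr1"][389] != "A" else "C")]
        _, _, skipped = build_custom_reference(chroms, models, muts)
        assert skipped and "outside" in skipped[0][1]

    def test_output_contains_only_mutated_genes(self, toy_reference):
        chroms, models = self._setup(toy_reference)
        ref = chroms["chr1"][119]
        muts = [make_mutation(gene="GA", pos=120, ref=ref, alt="A" if ref != "A" else "C")]
        pairs, _, _ = build_custom_reference(chroms, models, muts)
        assert {p.gene for p in pairs} == {"GA"}

    def test_mut_header_convention_and_sequence(self, toy_reference):
        chroms, models = self._setup(toy_reference)
        ref = chroms["chr1"][99]
        alt = "A" if ref != "A" else "C"
        muts = [make_mutation(gene="GA", pos=100, ref=ref, alt=alt)]
        (pair,), (entry,), _ = build_custom_reference(chroms, models, muts)
        assert pair.wt_header == ">GA" and pair.mut_header == ">GA_Mut"
        assert pair.mut_seq[entry.mut_pos - 1] == alt
        assert len(pair.wt_seq) == len(pair.mut_seq)

    def test_duplicate_gene_symbols_disambiguated(self, tmp_path, toy_reference):
        gtf = tmp_path / "dup.gtf"
        gtf.write_text(
            'chr1\tt\tgene\t51\t150\t.\t+\t.\tgene_id "GX.1"; gene_name "GX";\n'
            'chr1\tt\tgene\t200\t300\t.\t+\t.\tgene_id "GX.2"; gene_name "GX";\n'
        )
        models = load_gene_models(gtf)
        assert [m.gene for m in models] == ["GX", "GX#2"]
        chroms = toy_reference["chroms"]
        ref = chroms["chr1"][249]
        muts = [make_mutation(gene="GX", pos=250, ref=ref, alt="A" if ref != "A" else "C")]
        (pair,), (entry,), skipped = build_custom_reference(chroms, models, muts)
        assert not skipped and pair.gene == "GX#2" and entry.wt_contig == "GX#2"

    def test_index_roundtrip_through_tsv(self, tmp_path, toy_reference):
        chroms, models = self._setup(toy_reference)
        ref = chroms["chr1"][129]
        muts = [make_mutation(gene="GA", pos=130, ref=ref, alt="A" if ref != "A" else "C")]
        _, entries, _ = build_custom_reference(chroms, models, muts)
        path = tmp_path / "index.tsv"
        write_index(entries, path)
        back = read_index(path, sample_id="S1")
        assert [(e.wt_contig, e.wt_pos, e.mut_contig, e.mut_pos, e.shift) for e in back] == [
            (e.wt_contig, e.wt_pos, e.mut_contig, e.mut_pos, e.shift) for e in entries]
        assert back[0].mutation.pos == entries[0].mutation.pos
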