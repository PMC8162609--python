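import pytest

from pankit.annotation import translate
from pankit.seqio import (
    AnnotationSet,
    Feature,
    FormatError,
    ReadRecord,
    SeqRecord,
    read_fasta,
    read_fastq,
    read_gff3,
    write_fasta,
    write_fastq,
    write_gff3,
    write_pgap_inputs,
)


class TestFasta:
    def test_wrapped_lines_concatenate(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.id == "a" and rec.sequence == "ACGTACGT"

    def test_round_trip_identity(self, tmp_path):
        recs = [SeqRecord("a", "ACGT" * 50, "desc one"), SeqRecord("b", "TTGA")]
        p = tmp_path / "rt.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence, r.description) for r in back] == [
            (r.id, r.sequence, r.description) for r in recs
        ]

    def test_order_preserved_and_wrapping(self, tmp_path):
        p = tmp_path / "o.fasta"
        write_fasta([SeqRecord("a", "A" * 150), SeqRecord("b", "C" * 10)], p, width=70)
        lines = p.read_text().splitlines()
        assert lines[0] == ">a" and lines.count(">b") == 1
        assert lines.index(">a") < lines.index(">b")
        assert len([ln for ln in lines[1 : lines.index(">b")] if ln]) == 3  # 70+70+10

    @pytest.mark.parametrize(
        "content,match",
        [
            ("", "empty"),
            (">a\nACGT\n>a\nACGT\n", "duplicate"),
            (">a\nACXT\n", "non-IUPAC"),
            ("ACGT\n", "start with"),
        ],
    )
    def test_format_errors(self, tmp_path, content, match):
        p = tmp_path / "bad.fasta"
        p.write_text(content)
        with pytest.raises(FormatError, match=match):
            read_fasta(p)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a\nacgtn\n")
        assert read_fasta(p)[0].sequence == "ACGTN"

    def test_width_zero_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="width"):
            write_fasta([SeqRecord("a", "ACGT")], tmp_path / "w.fasta", width=0)


class TestFastq:
    def test_parse_basic(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        (r,) = read_fastq(p)
        assert (r.id, r.sequence, r.quality) == ("r1", "ACGT", "IIII")

    def test_round_trip_byte_exact_qualities(self, tmp_path):
        reads = [ReadRecord("a/1", "ACGTAC", '!"#$%I'), ReadRecord("b/2", "TTTT", "IIII")]
        p = tmp_path / "rt.fastq"
        write_fastq(reads, p)
        back = read_fastq(p)
        assert [(r.id, r.sequence, r.quality) for r in back] == [
            (r.id, r.sequence, r.quality) for r in reads
        ]

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(FormatError, match="length"):
            read_fastq(p)

    def test_truncated_record_rejected(self, tmp_path):
        p = tmp_path / "tr.fastq"
        p.write_text("@r1\nACGT\n+\n")
        with pytest.raises(FormatError, match="truncated"):
            read_fastq(p)


class TestGff3:
    def _ann(self):
        contig = SeqRecord("c1", "ATGAAATAA" + "TTAATTAATTA")  # 20 bp
        return AnnotationSet(
            "g", [contig], [Feature("g_00001", "c1", 1, 9, "+", product="recA")]
        )

    def test_round_trip(self, tmp_path):
        ann = self._ann()
        gff, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        write_gff3(ann, gff)
        write_fasta(ann.contigs, fasta)
        back = read_gff3(gff, fasta)
        assert len(back.features) == 1
        f = back.features[0]
        assert (f.feature_id, f.start, f.end, f.strand, f.product) == (
            "g_00001", 1, 9, "+", "recA",
        )

    def test_out_of_bounds_feature_rejected(self, tmp_path):
        gff, fasta = tmp_path / "b.gff3", tmp_path / "b.fasta"
        write_fasta([SeqRecord("c1", "A" * 20)], fasta)
        gff.write_text("##gff-version 3\nc1\tx\tCDS\t1\t25\t.\t+\t0\tID=f1\n")
        with pytest.raises(ValueError, match="beyond contig"):
            read_gff3(gff, fasta)

    def test_non_cds_lines_dropped(self, tmp_path):
        gff, fasta = tmp_path / "n.gff3", tmp_path / "n.fasta"
        write_fasta([SeqRecord("c1", "A" * 30)], fasta)
        gff.write_text(
            "##gff-version 3\nc1\tx\tgene\t1\t9\t.\t+\t0\tID=g1\n"
            "c1\tx\tCDS\t1\t9\t.\t+\t0\tID=f1\n"
        )
        back = read_gff3(gff, fasta)
        assert [f.feature_id for f in back.features] == ["f1"]


class TestPgapInputs:
    def test_translation_and_function_line(self, tmp_path):
        ann = AnnotationSet(
            "g",
            [SeqRecord("c1", "ATGAAATAA")],
            [Feature("g1", "c1", 1, 9, "+")],
        )
        pep, nuc, fun = write_pgap_inputs(ann, tmp_path / "g")
        assert "MK" in open(pep).read()
        assert "ATGAAATAA" in open(nuc).read()
        assert open(fun).read() == "g1\t-\thypothetical protein\n"

    def test_zero_cds_rejected(self, tmp_path):
        ann = AnnotationSet("g", [SeqRecord("c1", "ACGT")], [])
        with pytest.raises(ValueError, match="no CDS"):
            write_pgap_inputs(ann, tmp_path / "g")

    def test_three_files_conserve_count_and_order(self, tmp_path, small_panel):
        genomes, _ = small_panel
        _, ann = genomes[0]
        pep, nuc, fun = write_pgap_inputs(ann, tmp_path / "g")
        pep_ids = [ln[1:].split()[0] for ln in open(pep) if ln.startswith(">")]
        nuc_ids = [ln[1:].split()[0] for ln in open(nuc) if ln.startswith(">")]
        fun_ids = [ln.split("\t")[0] for ln in open(fun)]
        assert pep_ids == nuc_ids == fun_ids
        assert len(pep_ids) == len(ann.features)

    def test_pep_equals_translated_nuc(self, tmp_path, small_panel):
        genomes, _ = small_panel
        _, ann = genomes[1]
        pep, nuc, _ = write_pgap_inputs(ann, tmp_path / "g")
        peps = {r.id: r.sequence for r in read_fasta(pep, alphabet="protein")}
        nucs = {r.id: r.sequence for r in read_fasta(nuc)}
        for fid, seq in nucs.items():
            assert peps[fid] == translate(seq)

    def test_internal_stop_skipped_with_warning(self, tmp_path):
        ann = AnnotationSet(
            "g",
            [SeqRecord("c1", "ATGTAAATAAAT" + "ATGAAATAA")],
            [
                Feature("bad", "c1", 1, 9, "+"),   # ATGTAAATA -> internal stop
                Feature("ok", "c1", 13, 21, "+"),
            ],
        )
        with pytest.warns(UserWarning, match="internal stop"):
            pep, nuc, fun = write_pgap_inputs(ann, tmp_path / "g")
        assert [ln.split("\t")[0] for ln in open(fun)] == ["ok"]
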