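"""FASTA/FASTQ/SAM ingestion and the internal data model."""

import gzip

import pytest

import circinfer as ci
from circinfer import seqio
from circinfer.errors import (FormatError, MissingReferenceError,
                              PairingError)

SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:ref\tLN:50\n"


def write(path, text):
    path.write_text(text)
    return str(path)


class TestFasta:
    def test_case_normalization(self, tmp_path):
        recs = ci.read_fasta(write(tmp_path / "a.fa", ">x\nacgt\n"))
        assert [(r.id, r.sequence) for r in recs] == [("x", "ACGT")]

    def test_two_entries_order_preserved(self, tmp_path):
        recs = ci.read_fasta(write(tmp_path / "a.fa",
                                   ">x\nAAAA\n>y\nCCCC\n"))
        assert [r.id for r in recs] == ["x", "y"]

    def test_non_acgtn_mapped_to_n(self, tmp_path):
        recs = ci.read_fasta(write(tmp_path / "a.fa", ">x\nAC-GT\n"))
        assert recs[0].sequence == "ACNGT"

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">x\nACGT\n")
        assert ci.read_fasta(p)[0].sequence == "ACGT"

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ci.read_fasta(tmp_path / "nope.fa")

    def test_empty_file(self, tmp_path):
        with pytest.raises(FormatError):
            ci.read_fasta(write(tmp_path / "a.fa", ""))

    def test_malformed_header_names_line(self, tmp_path):
        with pytest.raises(FormatError, match="line 1"):
            ci.read_fasta(write(tmp_path / "a.fa", "ACGT\n"))

    def test_round_trip_identity(self, tmp_path, rng):
        bases = "ACGT"
        recs = [ci.SeqRecord(f"r{i}", "".join(
            bases[b] for b in rng.integers(0, 4, size=rng.integers(1, 200))))
            for i in range(5)]
        out = tmp_path / "rt.fa"
        ci.write_fasta(recs, out)
        back = ci.read_fasta(out)
        assert [(r.id, r.sequence) for r in back] == \
            [(r.id, r.sequence) for r in recs]


class TestFastq:
    def test_phred33_qualities(self, tmp_path):
        recs = ci.read_reads(write(tmp_path / "r.fq",
                                   "@r1\nACGT\n+\nIIII\n"))
        assert recs[0].qualities == [40, 40, 40, 40]

    def test_pairing_by_order(self, tmp_path):
        fq1 = "".join(f"@p{i}\nAAAA\n+\nIIII\n" for i in range(10))
        fq2 = "".join(f"@p{i}\nCCCC\n+\nIIII\n" for i in range(10))
        recs = ci.read_reads(write(tmp_path / "1.fq", fq1),
                             write(tmp_path / "2.fq", fq2))
        assert len(recs) == 20
        mates = [r.id for r in recs[:2]]
        assert mates == ["p0/1", "p0/2"]
        # every pair has exactly two mates with matching ids
        stems = {}
        for r in recs:
            stem, mate = r.id.rsplit("/", 1)
            stems.setdefault(stem, set()).add(mate)
        assert all(v == {"1", "2"} for v in stems.values())

    def test_unequal_mate_counts(self, tmp_path):
        fq1 = "".join(f"@p{i}\nAAAA\n+\nIIII\n" for i in range(10))
        fq2 = "".join(f"@p{i}\nCCCC\n+\nIIII\n" for i in range(9))
        with pytest.raises(PairingError):
            ci.read_reads(write(tmp_path / "1.fq", fq1),
                          write(tmp_path / "2.fq", fq2))


class TestSam:
    def test_simple_record(self, tmp_path):
        sam = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\tAS:i:0\n"
        alns = ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")
        assert len(alns) == 1
        a = alns[0]
        assert (a.ref_start, a.ref_end, a.score) == (0, 4, 0)

    def test_unmapped_skipped(self, tmp_path):
        sam = SAM_HEADER + \
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        alns = ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")
        assert alns == []

    def test_deletion_coordinates(self, tmp_path):
        # POS=3, 2M1D2M: reference interval [2,7), deletion at ref index 4
        sam = SAM_HEADER + \
            "r1\t0\tref\t3\t255\t2M1D2M\t*\t0\t0\tACGT\tIIII\tAS:i:-8\n"
        a = ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")[0]
        assert (a.ref_start, a.ref_end) == (2, 7)
        assert a.columns == "MMDMM"

    def test_soft_clip_dropped_hard_clip_rejected(self, tmp_path):
        sam = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t2S4M\t*\t0\t0\tTTACGT\tIIIIII\tAS:i:0\n"
        a = ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")[0]
        assert a.columns == "MMMM"
        assert (a.ref_start, a.ref_end) == (0, 4)
        bad = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t2H4M\t*\t0\t0\tACGT\tIIII\tAS:i:0\n"
        with pytest.raises(FormatError):
            ci.read_sam_alignments(write(tmp_path / "b.sam", bad), "ref")

    def test_missing_reference(self, tmp_path):
        sam = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\tAS:i:0\n"
        with pytest.raises(MissingReferenceError):
            ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "other")

    def test_score_recomputed_from_md(self, tmp_path):
        # one Q40 mismatch, no AS tag: score from MD under the default scheme
        sam = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\tMD:Z:2A1\n"
        a = ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")[0]
        assert a.score == -6
        assert a.columns == "MMXM"

    def test_no_score_source_is_error(self, tmp_path):
        sam = SAM_HEADER + \
            "r1\t0\tref\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\n"
        with pytest.raises(FormatError, match="AS:i"):
            ci.read_sam_alignments(write(tmp_path / "a.sam", sam), "ref")

    def test_write_read_round_trip(self, tmp_path, sim2k):
        reads = sim2k["reads"][:40]
        flipped, _, _ = ci.flip(sim2k["genome"])
        ref = ci.SeqRecord("flip", flipped)
        alns = ci.align_all(reads, flipped)
        path = tmp_path / "out.sam"
        seqio.write_sam(alns, ref, path, reads={r.id: r for r in reads})
        back = ci.read_sam_alignments(path, "flip")
        orig = [a for a in alns if a.mapped]
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert (a.read_id, a.ref_start, a.ref_end, a.score, a.strand) == \
                (b.read_id, b.ref_start, b.ref_end, b.score, b.strand)

    def test_intervals_within_reference(self, sim2k):
        flipped, _, _ = ci.flip(sim2k["genome"])
        alns = ci.align_all(sim2k["reads"][:100], flipped)
        for a in alns:
            if a.mapped:
                assert 0 <= a.ref_start < a.ref_end <= len(flipped)
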