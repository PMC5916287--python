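"""Reading and writing FASTA / FASTQ / SAM.

Thin adapters over Biopython (FASTA, FASTQ) and pysam (SAM) that normalize
records into the internal data model: 0-based half-open coordinates,
uppercase ACGTN sequences, Phred+33 qualities.  Gzip is handled
transparently for FASTA and FASTQ.
"""

from __future__ import annotations

import gzip
import os
from typing import IO

from Bio import SeqIO as _BioSeqIO
import pysam

from .errors import FormatError, MissingReferenceError, PairingError
from .model import ReadAlignment, SeqRecord, reverse_complement

__all__ = [
    "SeqRecord",
    "ReadAlignment",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "read_sam_alignments",
    "write_sam",
]

# CIGAR ops accepted on SAM ingestion.  Hard clips (H) and the exotic ops
# (N, P, B) are rejected: the pipeline's metrics are defined for
# end-to-end alignments only.
_SAM_OK_OPS = set("M=XIDS")


def _open_text(path: str | os.PathLike) -> IO[str]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Parse a (possibly gzipped) FASTA file into SeqRecords.

    Order is preserved; sequences are normalized to uppercase ACGTN.
    """
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FormatError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'"
            )
    with _open_text(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            records.append(SeqRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[SeqRecord], path: str | os.PathLike,
                descriptions: dict[str, str] | None = None,
                width: int = 70) -> None:
    """Write SeqRecords as FASTA, optionally with per-id description text."""
    with open(path, "wt") as fh:
        for rec in records:
            desc = (descriptions or {}).get(rec.id, "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _read_fastq(path: str | os.PathLike, suffix: str = "") -> list[SeqRecord]:
    out: list[SeqRecord] = []
    with _open_text(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fastq"):
            out.append(SeqRecord(
                id=rec.id + suffix,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
            ))
    if not out:
        raise FormatError(f"{path}: no FASTQ records")
    return out


def read_reads(path1: str | os.PathLike,
               path2: str | os.PathLike | None = None) -> list[SeqRecord]:
    """Read single-end or paired-end FASTQ (Phred+33).

    With two files, mates are associated by order and tagged ``/1`` and
    ``/2`` (unless already tagged); counts must agree.  The returned list
    interleaves mates: r1/1, r1/2, r2/1, r2/2, ...
    """
    def tag(rec: SeqRecord, mate: int) -> SeqRecord:
        if rec.id.endswith(("/1", "/2")):
            return rec
        rec.id = f"{rec.id}/{mate}"
        return rec

    if path2 is None:
        return _read_fastq(path1)
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise PairingError(
            f"mate files differ in record count: {len(r1)} vs {len(r2)}"
        )
    out: list[SeqRecord] = []
    for a, b in zip(r1, r2):
        out.append(tag(a, 1))
        out.append(tag(b, 2))
    return out


def _columns_from_pysam(aln: "pysam.AlignedSegment") -> str:
    """Expand a pysam record into M/X/I/D columns (soft clips dropped).

    Match/mismatch is resolved from =/X ops when present, else from the MD
    tag via aligned pairs; with neither, M is recorded as match.
    """
    cols: list[str] = []
    has_md = aln.has_tag("MD")
    if has_md:
        # aligned_pairs with_seq gives lowercase ref base on mismatch
        pairs = aln.get_aligned_pairs(with_seq=True)
        for qpos, rpos, ref_base in pairs:
            if qpos is not None and rpos is not None:
                cols.append("X" if (ref_base is not None and ref_base.islower()
                                    or ref_base is None) else "M")
            elif qpos is not None:  # no ref base: insertion or soft clip
                cols.append("I")
            else:
                cols.append("D")
        # strip soft-clip "insertions" at the two ends using cigar info
        cig = aln.cigartuples or []
        lead = cig[0][1] if cig and cig[0][0] == 4 else 0
        tail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
        return "".join(cols[lead:len(cols) - tail if tail else None])
    for op, length in aln.cigartuples or []:
        ch = "MIDNSHP=XB"[op]
        if ch not in _SAM_OK_OPS:
            raise FormatError(
                f"read {aln.query_name!r}: unsupported CIGAR op {ch!r}"
            )
        if ch == "S":
            continue
        cols.append({"M": "M", "=": "M", "X": "X", "I": "I", "D": "D"}[ch] * length)
    return "".join(cols)


def _score_from_columns(columns: str, qualities, scheme) -> int:
    from .aligner import ScoringScheme  # local import: avoid cycle at module load

    scheme = scheme or ScoringScheme()
    score = 0
    qpos = 0
    prev = ""
    for c in columns:
        if c in "MXI":
            q = qualities[qpos] if qualities is not None else 40
            qpos += 1
        if c == "X":
            score -= scheme.mismatch_penalty(q)
        elif c in "ID":
            # an I->D (or D->I) transition starts a new gap
            score -= scheme.gap_extend + (scheme.gap_open if prev != c else 0)
        prev = c
    return score


def read_sam_alignments(path: str | os.PathLike, reference_id: str,
                        scheme=None) -> list[ReadAlignment]:
    """Ingest mapped records from a SAM file produced by an external mapper.

    Unmapped records and records mapped to other references are skipped.
    The alignment score is taken from the standard ``AS:i`` tag as-is (the
    producer's scale is preserved); for records lacking ``AS:i`` the score
    is recomputed from the MD tag under ``scheme`` (default scheme if
    None), and a record with neither is a format error.
    """
    path = os.fspath(path)
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        if reference_id not in (sam.references or ()):
            raise MissingReferenceError(
                f"reference {reference_id!r} not in SAM header "
                f"(found: {list(sam.references or ())})"
            )
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.reference_name != reference_id:
                continue
            cig = aln.cigartuples or []
            for op, _ in cig:
                ch = "MIDNSHP=XB"[op]
                if ch not in _SAM_OK_OPS:
                    raise FormatError(
                        f"read {aln.query_name!r}: unsupported CIGAR op {ch!r}"
                    )
            columns = _columns_from_pysam(aln)
            if aln.has_tag("AS"):
                score = int(aln.get_tag("AS"))
                note = "AS:i from SAM"
            elif aln.has_tag("MD"):
                score = _score_from_columns(columns, aln.query_qualities, scheme)
                note = "score recomputed from MD"
            else:
                raise FormatError(
                    f"read {aln.query_name!r}: neither AS:i nor MD present; "
                    "cannot determine alignment score"
                )
            name = aln.query_name
            if aln.is_paired and not name.endswith(("/1", "/2")):
                name += "/1" if aln.is_read1 else "/2"
            out.append(ReadAlignment(
                read_id=name,
                ref_start=aln.reference_start,  # pysam is already 0-based
                ref_end=aln.reference_end,
                columns=columns,
                score=score,
                mapped=True,
                strand="-" if aln.is_reverse else "+",
                note=note,
            ))
    return out


def write_sam(alignments: list[ReadAlignment], reference: SeqRecord,
              path: str | os.PathLike,
              reads: dict[str, SeqRecord] | None = None) -> None:
    """Write internal alignments as SAM with a minimal header and AS:i tags."""
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": reference.id, "LN": len(reference)}]}
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as sam:
        for a in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = a.read_id
            if not a.mapped:
                seg.is_unmapped = True
                sam.write(seg)
                continue
            seg.reference_id = 0
            seg.reference_start = a.ref_start
            seg.mapping_quality = 255
            seg.is_reverse = a.strand == "-"
            cigar = []
            for c in a.columns:
                op = {"M": 0, "X": 0, "I": 1, "D": 2}[c]
                if cigar and cigar[-1][0] == op:
                    cigar[-1][1] += 1
                else:
                    cigar.append([op, 1])
            seg.cigartuples = [tuple(t) for t in cigar]
            if reads and a.read_id in reads:
                rec = reads[a.read_id]
                seq, quals = rec.sequence, rec.qualities
                if a.strand == "-":  # SAM stores reference orientation
                    seq = reverse_complement(seq)
                    quals = quals[::-1] if quals is not None else None
                seg.query_sequence = seq
                if quals is not None:
                    seg.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in quals))
            seg.set_tag("AS", a.score)
            sam.write(seg)
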