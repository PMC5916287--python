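"""Per-position profiles and the circularity verdict.

Coverage counts, for each reference position, the reads whose alignment
places a read base there (match or mismatch; deletion columns do not
count).  Connectivity is stricter: a read supports position i only if it
places read bases on i-1, i and i+1 with those three columns consecutive
in the read — no insertion or deletion between them.  Reads that start or
end at a position therefore never support it, and neither do reads gapped
across it; this is what makes a single indel at the flip junction
detectable.  The two reference ends always have connectivity 0.

The verdict is PASS when the minimum connectivity inside a window around
the junction reaches ``min_connectivity`` both absolutely and relative to
the profile-wide median (a junction supported at less than
``low_connectivity_fraction`` of the median is rejected — an absolute
floor alone cannot work across coverages, because a junction indel
absorbed inside a homopolymer still collects a few gapless reads starting
within the run, and that number grows with coverage), and the average
alignment score of mapped reads stays above ``score_floor``.  An average
score of -3 or lower is flagged for manual review regardless of the
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, UndefinedMetricError
from .model import PositionProfile, ReadAlignment

__all__ = [
    "Thresholds",
    "CircularityReport",
    "coverage_profile",
    "connectivity_profile",
    "position_profile",
    "similarity",
    "summarize",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the circularity verdict.

    ``junction_window`` is the half-width w of the examined window
    ``[junction_index - w + 1, junction_index + w]``; None derives
    w = read length - 1 from the alignments, so every adjacency a
    junction-spanning read could attest is examined.
    ``low_connectivity_fraction`` is the required minimum junction
    connectivity as a fraction of the profile-wide median.
    """

    min_connectivity: int = 2
    score_floor: float = -3.0
    junction_window: int | None = None
    low_connectivity_fraction: float = 0.25


@dataclass
class CircularityReport:
    """Summary metrics and PASS/FAIL verdict for one flipped candidate."""

    length: int
    n_reads: int
    n_mapped: int
    mean_coverage: float
    average_alignment_score: float | None
    similarity: float | None
    junction_index: int
    junction_window: tuple[int, int]
    min_junction_connectivity: int
    mean_junction_connectivity: float
    verdict: str
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["junction_window"] = list(self.junction_window)
        return d


def _iter_runs(aln: ReadAlignment):
    """Yield (ref_start, ref_end) of maximal gap-free match/mismatch runs."""
    pos = aln.ref_start
    run_start = None
    for c in aln.columns:
        if c in "MX":
            if run_start is None:
                run_start = pos
            pos += 1
        else:
            if run_start is not None:
                yield run_start, pos
                run_start = None
            if c == "D":
                pos += 1
            # I consumes read only; it still breaks the run
    if run_start is not None:
        yield run_start, pos


def _check_bounds(aln: ReadAlignment, length: int) -> None:
    if aln.ref_start < 0 or aln.ref_end > length:
        raise ConsistencyError(
            f"alignment {aln.read_id!r} interval [{aln.ref_start},"
            f"{aln.ref_end}) outside reference of length {length}"
        )


def coverage_profile(alignments: list[ReadAlignment], length: int) -> np.ndarray:
    """Per-position count of reads placing a read base on the position."""
    cov = np.zeros(length, dtype=np.int32)
    for aln in alignments:
        if not aln.mapped:
            continue
        _check_bounds(aln, length)
        if aln.n_gap_columns == 0:
            cov[aln.ref_start:aln.ref_end] += 1
        else:
            for a, b in _iter_runs(aln):
                cov[a:b] += 1
    return cov


def connectivity_profile(alignments: list[ReadAlignment],
                         length: int) -> np.ndarray:
    """Per-position count of reads supporting both neighbor adjacencies.

    Within a gap-free run covering [a, b), the supported positions are
    [a+1, b-1): interior positions whose left and right neighbors are
    covered by read bases consecutive in the read.
    """
    conn = np.zeros(length, dtype=np.int32)
    for aln in alignments:
        if not aln.mapped:
            continue
        _check_bounds(aln, length)
        if aln.n_gap_columns == 0:
            conn[aln.ref_start + 1:max(aln.ref_start + 1, aln.ref_end - 1)] += 1
        else:
            for a, b in _iter_runs(aln):
                conn[a + 1:max(a + 1, b - 1)] += 1
    if length >= 1:
        conn[0] = 0
        conn[length - 1] = 0
    return conn


def position_profile(alignments: list[ReadAlignment],
                     length: int) -> PositionProfile:
    return PositionProfile(
        length=length,
        coverage=coverage_profile(alignments, length),
        connectivity=connectivity_profile(alignments, length),
    )


def similarity(alignments: list[ReadAlignment]) -> float:
    """Percent match columns among match+mismatch columns of mapped reads."""
    match = mismatch = 0
    for aln in alignments:
        if not aln.mapped:
            continue
        match += aln.columns.count("M")
        mismatch += aln.columns.count("X")
    if match + mismatch == 0:
        raise UndefinedMetricError("no mapped reads: similarity undefined")
    return 100.0 * match / (match + mismatch)


def _derive_window(alignments: list[ReadAlignment]) -> int:
    lengths = [a.read_length for a in alignments if a.mapped]
    return max(lengths) - 1 if lengths else 1


def summarize(alignments: list[ReadAlignment], profile: PositionProfile,
              junction_index: int,
              thresholds: Thresholds | None = None) -> CircularityReport:
    """Render the circularity verdict for one flipped candidate.

    ``profile`` must have been computed from the same alignments.
    """
    th = thresholds or Thresholds()
    length = profile.length
    mapped = [a for a in alignments if a.mapped]
    cov = np.asarray(profile.coverage)
    conn = np.asarray(profile.connectivity)

    w = th.junction_window if th.junction_window is not None \
        else _derive_window(alignments)
    lo = max(1, junction_index - w + 1)
    hi = min(length - 2, junction_index + w)
    window = (lo, hi)

    if not mapped:
        return CircularityReport(
            length=length, n_reads=len(alignments), n_mapped=0,
            mean_coverage=0.0, average_alignment_score=None, similarity=None,
            junction_index=junction_index, junction_window=window,
            min_junction_connectivity=0, mean_junction_connectivity=0.0,
            verdict="FAIL", flags=["no mapped reads"],
        )

    avg_score = float(np.mean([a.score for a in mapped]))
    sim = similarity(alignments)
    mean_cov = float(cov.sum()) / length
    win = conn[lo:hi + 1]
    min_jc = int(win.min()) if win.size else 0
    mean_jc = float(win.mean()) if win.size else 0.0

    interior = conn[1:length - 1]
    median_conn = float(np.median(interior)) if interior.size else 0.0
    relative_ok = min_jc >= th.low_connectivity_fraction * median_conn
    verdict = ("PASS" if min_jc >= th.min_connectivity and relative_ok
               and avg_score > th.score_floor else "FAIL")
    flags: list[str] = []
    if avg_score <= -3.0:
        flags.append("score <= -3: review recommended")
    if median_conn > 0 and not relative_ok:
        flags.append(
            f"junction connectivity {min_jc} below "
            f"{th.low_connectivity_fraction:.0%} of profile median "
            f"({median_conn:.1f})"
        )

    return CircularityReport(
        length=length, n_reads=len(alignments), n_mapped=len(mapped),
        mean_coverage=mean_cov, average_alignment_score=avg_score,
        similarity=sim, junction_index=junction_index,
        junction_window=window, min_junction_connectivity=min_jc,
        mean_junction_connectivity=mean_jc, verdict=verdict, flags=flags,
    )
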