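"""Extraction of a putative circular sequence from an assembly scaffold.

De novo assemblers that walk around a circular molecule past its origin
leave the origin-adjacent sequence duplicated inside the final scaffold,
often with spurious flanking sequence on either side.  This module finds
identical k-mers separated by at least a minimum span, takes the widest
such pair as delimiting one full traversal of the circle, and "flips"
(rotates by half the length) the extracted candidate so that the original
5' and 3' ends become adjacent in the middle — where ordinary linear read
mapping can interrogate the junction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateInputError, NoCircularityCandidate
from .model import SeqRecord

__all__ = [
    "KmerPair",
    "PutativeCircle",
    "find_duplicate_kmers",
    "extract_circle",
    "flip",
    "base_composition",
]


@dataclass(frozen=True)
class KmerPair:
    """Two identical k-mers on the same strand of a scaffold.

    ``span = right_start - left_start`` is the length of the circular
    candidate the pair delimits.
    """

    k: int
    left_start: int
    right_start: int

    @property
    def span(self) -> int:
        return self.right_start - self.left_start


@dataclass
class PutativeCircle:
    """A circular candidate cut out of a scaffold, plus its flipped form.

    ``sequence`` is one full traversal of the putative circle (the second
    copy of the delimiting k-mer is excluded, so the junction is
    seamless).  ``flipped`` is ``sequence`` rotated by ``flip_offset =
    floor(L/2)``; ``junction_index`` is the 0-based position in
    ``flipped`` of the base that was originally last — the junction lies
    between ``junction_index`` and ``junction_index + 1``.
    """

    sequence: str
    source_interval: tuple[int, int]
    k_used: int
    flipped: str
    flip_offset: int
    junction_index: int


def find_duplicate_kmers(scaffold: SeqRecord | str, k: int,
                         min_span: int) -> list[KmerPair]:
    """All ordered pairs of identical k-mers at span >= min_span.

    Sorted by decreasing span, then increasing left_start.  K-mers
    containing N never match (N is absence of evidence, not identity).
    An empty list is a valid result.
    """
    seq = scaffold.sequence if isinstance(scaffold, SeqRecord) else scaffold
    if not 1 <= k <= len(seq):
        raise DegenerateInputError(f"k={k} outside [1, {len(seq)}]")
    if min_span < k:
        raise DegenerateInputError(f"min_span={min_span} < k={k}")
    positions: dict[str, list[int]] = {}
    for p in range(len(seq) - k + 1):
        kmer = seq[p:p + k]
        if "N" in kmer:
            continue
        positions.setdefault(kmer, []).append(p)
    pairs: list[KmerPair] = []
    for pos in positions.values():
        if len(pos) < 2:
            continue
        for i, left in enumerate(pos):
            for right in pos[i + 1:]:
                if right - left >= min_span:
                    pairs.append(KmerPair(k, left, right))
    pairs.sort(key=lambda p: (-p.span, p.left_start))
    return pairs


def flip(circle_sequence: str) -> tuple[str, int, int]:
    """Rotate a circular sequence by half its length.

    Returns ``(flipped, flip_offset, junction_index)`` with
    ``flip_offset = floor(L/2)`` and ``flipped = seq[flip_offset:] +
    seq[:flip_offset]``.  The original last base lands at
    ``junction_index = L - flip_offset - 1``; the original first base is
    at ``junction_index + 1``.  Rotating ``flipped`` by
    ``L - flip_offset`` restores the input.
    """
    length = len(circle_sequence)
    if length < 2:
        raise DegenerateInputError("cannot flip a sequence shorter than 2")
    offset = length // 2
    flipped = circle_sequence[offset:] + circle_sequence[:offset]
    return flipped, offset, length - offset - 1


def extract_circle(scaffold: SeqRecord | str, k: int,
                   min_span: int) -> PutativeCircle:
    """Extract the most extended putative circular sequence.

    Takes the duplicated-k-mer pair with the largest span (ties: smallest
    left_start) and cuts ``scaffold[left_start:right_start]`` — exactly
    one copy of the duplicated k-mer is retained so the in-circle
    junction is seamless.  Raises :class:`NoCircularityCandidate` (with
    the widest span seen, if any) when nothing qualifies.
    """
    seq = scaffold.sequence if isinstance(scaffold, SeqRecord) else scaffold
    pairs = find_duplicate_kmers(seq, k, min_span)
    if not pairs:
        widest = None
        below = find_duplicate_kmers(seq, k, k)
        if below:
            widest = below[0].span
        raise NoCircularityCandidate(
            f"no duplicated {k}-mer at span >= {min_span}"
            + (f" (widest span found: {widest})" if widest else ""),
            largest_span=widest,
        )
    best = pairs[0]
    circle = seq[best.left_start:best.right_start]
    flipped, offset, junction = flip(circle)
    return PutativeCircle(
        sequence=circle,
        source_interval=(best.left_start, best.right_start),
        k_used=k,
        flipped=flipped,
        flip_offset=offset,
        junction_index=junction,
    )


def base_composition(sequence: str) -> dict[str, float]:
    """Percentages of A, C, G, T and GC over non-N bases, rounded to 2 dp.

    GC is computed as C% + G% before rounding.
    """
    counts = {b: sequence.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise DegenerateInputError("empty or all-N sequence")
    pct = {b: 100.0 * c / total for b, c in counts.items()}
    out = {b: round(pct[b], 2) for b in "ACGT"}
    out["GC"] = round(pct["C"] + pct["G"], 2)
    return out
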