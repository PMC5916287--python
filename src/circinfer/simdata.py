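"""Synthetic circular genomes, wrap-around reads, and scaffold artifacts.

The generator emulates the situation the pipeline is built for: a
circular molecule sequenced with paired-end short reads (fragment starts
uniform on the circle, so reads wrap the origin), assembled by an
iterative mapper that walks past the origin — leaving the origin-adjacent
sequence duplicated at the scaffold's 3' end — and flanked by spurious
random sequence on both sides.

Reads are generated from the true circle, not the scaffold: the reads
attest the junction that the linear scaffold hides, which is exactly the
evidence the circularity test exploits.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .model import SeqRecord, reverse_complement

__all__ = [
    "SimTruth",
    "simulate_circular_genome",
    "simulate_reads",
    "build_artifact_scaffold",
    "rotation_equivalent",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimTruth:
    """Ground truth of one simulated scaffold (everything reconstructable)."""

    genome: str
    rotation: int
    dup_len: int
    flank5: int
    flank3: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(asdict(self), fh, indent=2)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_circular_genome(length: int, gc: float, seed) -> str:
    """I.i.d. random circular genome with the given GC fraction.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2; deterministic given
    the seed.
    """
    if length < 1:
        raise DegenerateInputError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ConfigurationError("gc must be in [0, 1]")
    rng = _rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return _BASES[codes].tobytes().decode()


def simulate_reads(genome: str, coverage: float, read_length: int,
                   insert_mean: float = 300.0, insert_sd: float = 30.0,
                   sub_rate: float = 0.0, seed=0,
                   error_quality: int | None = 8,
                   quality: int = 40) -> list[SeqRecord]:
    """Paired-end reads from a circular genome (fragments wrap the origin).

    Pair count = ceil(coverage * length / (2 * read_length)).  Fragment
    starts are uniform on the circle; mate 1 is the fragment's 5' end,
    mate 2 the reverse complement of its 3' end.  Substitutions are
    i.i.d. at ``sub_rate`` (to a uniformly chosen different base);
    qualities are constant ``quality`` except erroneous bases, which get
    ``error_quality`` (default 8 — miscalled bases in real libraries
    carry low quality, and a mapper's quality-scaled mismatch penalties
    presuppose exactly that; pass None to keep errors at full quality).
    Returns interleaved mates tagged /1, /2.
    """
    length = len(genome)
    if read_length > length:
        raise ConfigurationError("read_length exceeds genome length")
    if insert_mean < read_length:
        raise ConfigurationError("insert_mean must be >= read_length")
    rng = _rng(seed)
    n_pairs = math.ceil(coverage * length / (2 * read_length))
    codes = np.frombuffer(genome.encode(), dtype=np.uint8)
    # work on the doubled circle so slices never wrap
    doubled = np.concatenate([codes, codes])

    starts = rng.integers(0, length, size=n_pairs)
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
        read_length, length)
    offsets = np.arange(read_length)
    m1 = doubled[starts[:, None] + offsets]                        # fragment 5'
    ends = starts + inserts - read_length
    m2_fwd = doubled[ends[:, None] + offsets]                      # fragment 3'

    def mutate(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if sub_rate <= 0:
            return mat, np.zeros(mat.shape, dtype=bool)
        mask = rng.random(mat.shape) < sub_rate
        # shift by 1..3 in base space: always a different base
        shift = rng.integers(1, 4, size=mat.shape)
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        inv = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            inv[b] = i
        out = mat.copy()
        out[mask] = lut[(inv[mat[mask]] + shift[mask]) % 4]
        return out, mask

    m1, err1 = mutate(m1)
    m2_fwd, err2 = mutate(m2_fwd)

    reads: list[SeqRecord] = []
    for i in range(n_pairs):
        s1 = m1[i].tobytes().decode()
        q1 = np.full(read_length, quality, dtype=int)
        s2 = m2_fwd[i].tobytes().decode()
        q2 = np.full(read_length, quality, dtype=int)
        if error_quality is not None:
            q1[err1[i]] = error_quality
            q2[err2[i]] = error_quality
        # mate 2 is sequenced from the other strand
        s2 = reverse_complement(s2)
        q2 = q2[::-1]
        reads.append(SeqRecord(f"sim_{i}/1", s1, list(q1)))
        reads.append(SeqRecord(f"sim_{i}/2", s2, list(q2)))
    return reads


def build_artifact_scaffold(genome: str, rotation: int = 0,
                            dup_len: int = 300, flank5: int = 0,
                            flank3: int = 0, seed=0
                            ) -> tuple[SeqRecord, SimTruth]:
    """Linear scaffold with assembler-style artifacts from a circular truth.

    scaffold = random(flank5) + R + R[:dup_len] + random(flank3), where R
    is the genome rotated by ``rotation``: one full traversal of the
    circle, its first ``dup_len`` bases duplicated at the 3' end, with
    spurious random flanks.
    """
    length = len(genome)
    if not 0 < dup_len < length:
        raise ConfigurationError("dup_len must be in (0, genome length)")
    if not 0 <= rotation < length:
        raise ConfigurationError("rotation must be in [0, genome length)")
    rng = _rng(seed)
    rotated = genome[rotation:] + genome[:rotation]

    def random_flank(k: int) -> str:
        if k == 0:
            return ""
        return _BASES[rng.integers(0, 4, size=k)].tobytes().decode()

    scaffold = random_flank(flank5) + rotated + rotated[:dup_len] \
        + random_flank(flank3)
    truth = SimTruth(genome=genome, rotation=rotation, dup_len=dup_len,
                     flank5=flank5, flank3=flank3,
                     seed=seed if isinstance(seed, int) else -1)
    return SeqRecord("sim_scaffold", scaffold), truth


def rotation_equivalent(candidate: str, genome: str) -> bool:
    """True iff candidate is a rotation of genome (same length, substring
    of the doubled genome)."""
    return len(candidate) == len(genome) and candidate in genome + genome
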