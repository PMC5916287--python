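"""Permutation study: sensitivity and false positives of the verdict.

The validation experiment perturbs the two 50-bp end windows of the
unflipped circular candidate with random single-base insertions or
deletions at a per-base probability, re-flips the perturbed sequence,
re-maps all reads and recomputes the circularity report.  Because the
perturbed windows sit at the candidate's ends, every edit lands in the
junction region of the flipped sequence — exactly where a wrong
circularization would be betrayed.  Results are ranked by distance to the
unperturbed baseline in (similarity, junction connectivity, average
alignment score) space.

With a per-base probability p over 2 x window positions an iteration can
draw zero edits; such an entry is byte-identical to the baseline and
trivially passes, so pass/false-positive tallies count only entries with
``edits_made > 0`` (zero-edit entries are reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import aligner, metrics
from .circtrim import PutativeCircle, flip
from .errors import ConfigurationError, DegenerateInputError
from .metrics import CircularityReport, Thresholds
from .model import SeqRecord

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "perturb_ends",
    "run_permutation_study",
    "rank_by_distance",
    "summarize_study",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PermutationConfig:
    """Design of the perturbation experiment.

    Defaults reproduce the standard design: 50-bp end windows, 1% and 5%
    per-base probabilities, insertion and deletion operations, 100
    repetitions per condition — 400 perturbed iterations plus one
    baseline.
    """

    window: int = 50
    probabilities: tuple[float, ...] = (0.01, 0.05)
    operations: tuple[str, ...] = ("insertion", "deletion")
    reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.probabilities:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        for op in self.operations:
            if op not in ("insertion", "deletion"):
                raise ConfigurationError(f"unknown operation {op!r}")

    @property
    def total_iterations(self) -> int:
        return len(self.probabilities) * len(self.operations) * self.reps


@dataclass
class PermutationResult:
    """Metrics of one perturbed-and-reflipped iteration."""

    iteration: int
    probability: float
    operation: str
    edits_made: int
    report: CircularityReport
    distance: float | None = None
    distance_rank: int | None = None
    is_baseline: bool = False


def perturb_ends(sequence: str, window: int, probability: float,
                 operation: str, rng: np.random.Generator
                 ) -> tuple[str, int]:
    """Randomly edit the first and last ``window`` bases of a sequence.

    Each in-window position is independently modified with the given
    probability: deletion removes the base; insertion places one uniform
    random base immediately after it.  Returns the modified sequence and
    the number of edits made.
    """
    length = len(sequence)
    if length < 2 * window:
        raise DegenerateInputError(
            f"sequence of length {length} shorter than 2 x window ({window})"
        )
    if operation not in ("insertion", "deletion"):
        raise ConfigurationError(f"unknown operation {operation!r}")
    targets = list(range(window)) + list(range(length - window, length))
    hits = rng.random(len(targets)) < probability
    edit_at = {pos for pos, h in zip(targets, hits) if h}
    out: list[str] = []
    for i, base in enumerate(sequence):
        if i in edit_at:
            if operation == "deletion":
                continue
            out.append(base)
            out.append(_BASES[rng.integers(4)])
        else:
            out.append(base)
    return "".join(out), len(edit_at)


def _evaluate(flipped: str, junction_index: int, reads: list[SeqRecord],
              scheme: aligner.ScoringScheme,
              thresholds: Thresholds) -> CircularityReport:
    alignments = aligner.align_all(reads, flipped, scheme)
    profile = metrics.position_profile(alignments, len(flipped))
    return metrics.summarize(alignments, profile, junction_index, thresholds)


def run_permutation_study(circle: PutativeCircle | str,
                          reads: list[SeqRecord],
                          config: PermutationConfig | None = None,
                          scheme: aligner.ScoringScheme | None = None,
                          thresholds: Thresholds | None = None,
                          ) -> list[PermutationResult]:
    """Run the full perturbation experiment.

    Returns one baseline entry (probability 0, iteration 0) followed by
    ``|probabilities| x |operations| x reps`` perturbed entries, each with
    ``distance_rank`` filled against the baseline.  Reproducible given
    ``config.seed``: each iteration draws from its own substream derived
    from (seed, iteration index).
    """
    config = config or PermutationConfig()
    scheme = scheme or aligner.ScoringScheme()
    thresholds = thresholds or Thresholds()
    sequence = circle.sequence if isinstance(circle, PutativeCircle) else circle
    if len(sequence) < 2 * config.window:
        raise ConfigurationError(
            f"circle of length {len(sequence)} shorter than twice the "
            f"perturbation window ({config.window})"
        )

    flipped, _, junction = flip(sequence)
    baseline_report = _evaluate(flipped, junction, reads, scheme, thresholds)
    results = [PermutationResult(
        iteration=0, probability=0.0, operation="none", edits_made=0,
        report=baseline_report, is_baseline=True,
    )]

    iteration = 0
    for probability in config.probabilities:
        for operation in config.operations:
            for _ in range(config.reps):
                iteration += 1
                rng = np.random.default_rng([config.seed, iteration])
                perturbed, edits = perturb_ends(
                    sequence, config.window, probability, operation, rng)
                if edits == 0:
                    report = baseline_report
                else:
                    f, _, j = flip(perturbed)
                    report = _evaluate(f, j, reads, scheme, thresholds)
                results.append(PermutationResult(
                    iteration=iteration, probability=probability,
                    operation=operation, edits_made=edits, report=report,
                ))
    return rank_by_distance(results, baseline_report)


def rank_by_distance(results: list[PermutationResult],
                     baseline: CircularityReport) -> list[PermutationResult]:
    """Fill each result's distance to baseline and its rank (1 = closest).

    Distance is the Euclidean norm of the deltas in similarity, mean
    junction connectivity and average alignment score, each standardized
    by the absolute baseline value (or 1 when that is 0).  Ties share the
    smaller rank.
    """
    def axes(report: CircularityReport) -> tuple[float, float, float]:
        return (
            report.similarity if report.similarity is not None else 0.0,
            report.mean_junction_connectivity,
            report.average_alignment_score
            if report.average_alignment_score is not None else float("-inf"),
        )

    base = axes(baseline)
    scale = [abs(v) if abs(v) > 0 else 1.0 for v in base]
    for res in results:
        vals = axes(res.report)
        if vals[2] == float("-inf"):
            res.distance = float("inf")
            continue
        res.distance = float(np.sqrt(sum(
            ((v - b) / s) ** 2 for v, b, s in zip(vals, base, scale))))
    finite = [r.distance if np.isfinite(r.distance) else np.inf
              for r in results]
    ranks = rankdata(finite, method="min")
    for res, rank in zip(results, ranks):
        res.distance_rank = int(rank)
    return results


def summarize_study(results: list[PermutationResult]) -> dict:
    """Pass counts per condition and the overall false-positive rate.

    A false positive is a perturbed entry with ``edits_made > 0`` whose
    verdict is PASS; zero-edit entries (identical to baseline) are
    tallied separately and never count as false positives.
    """
    perturbed = [r for r in results if not r.is_baseline]
    edited = [r for r in perturbed if r.edits_made > 0]
    conditions: dict[str, dict] = {}
    for r in perturbed:
        key = f"{r.operation}@{r.probability:g}"
        c = conditions.setdefault(key, {
            "iterations": 0, "edited": 0, "zero_edit": 0, "pass_edited": 0,
        })
        c["iterations"] += 1
        if r.edits_made > 0:
            c["edited"] += 1
            if r.report.passed:
                c["pass_edited"] += 1
        else:
            c["zero_edit"] += 1
    false_positives = sum(1 for r in edited if r.report.passed)
    baseline = next((r for r in results if r.is_baseline), None)
    return {
        "baseline_verdict": baseline.report.verdict if baseline else None,
        "iterations": len(perturbed),
        "edited_iterations": len(edited),
        "zero_edit_iterations": len(perturbed) - len(edited),
        "false_positives": false_positives,
        "false_positive_rate_percent": (
            100.0 * false_positives / len(edited) if edited else 0.0),
        "conditions": conditions,
    }
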