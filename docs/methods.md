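# Methods

## The problem

De novo assembly of a circular molecule (a mitochondrial genome, a
plasmid, a viral episome) produces a *linear* scaffold. When the
assembler walks around the circle past its origin, the origin-adjacent
sequence appears twice in the scaffold, and iterative baiting assemblers
frequently attach spurious flanking sequence on both sides. Deciding
whether the assembly truly represents a closed circle — and where the
circle's boundaries lie inside the scaffold — is the problem this
package addresses. The decisive evidence is in the original reads: a
genuinely circular molecule yields reads that span the join between the
sequence's two ends, and no amount of scaffold inspection substitutes
for them.

## Pipeline

1. **Trim** (`circtrim`). Search the scaffold for pairs of identical
   k-mers (same strand, no N) separated by at least `min_span` bases.
   The widest-span pair is taken to delimit one full traversal of the
   circle: the candidate is `scaffold[left:right]`, which contains
   exactly one copy of the duplicated k-mer so the implied junction is
   seamless. Ties on span prefer the pair closest to the scaffold 5'
   end — a deterministic rule where any would do.
2. **Flip** (`circtrim.flip`). Rotate the candidate by `floor(L/2)` so
   the original last and first bases become adjacent in the middle of
   the sequence. Linear read mapping can then interrogate the junction
   like any other position. The junction sits between `junction_index =
   L - floor(L/2) - 1` and the next position.
3. **Map** (`aligner`). Align every read end-to-end (the whole read must
   align; the reference interval is free) on both strands. Scores are
   0 for a perfect alignment and negative otherwise.
4. **Decide** (`metrics`). Compute per-position coverage and
   *connectivity*, the average alignment score and the percent
   similarity; PASS iff the minimum connectivity in a window around the
   junction reaches `min_connectivity` and the average score stays above
   `score_floor`.
5. **Validate** (`permute`). Perturb the candidate's end windows with
   random indels, re-flip, re-map, and tally how often a perturbed —
   hence non-circular — sequence still passes.

## Alignment model

Penalties (all configurable on `ScoringScheme`):

| parameter | default | meaning |
|---|---|---|
| `mismatch_min` / `mismatch_max` | 2 / 6 | mismatch penalty at base quality 0 / >= 40, linearly interpolated: `min + floor((max-min) * min(Q,40)/40)` |
| `n_penalty` | 1 | any column involving N |
| `gap_open` + `gap_extend` | 5 + 3/base | a length-g gap costs 5 + 3g |
| `min_score` | `floor(-(0.6 + 0.6 L))` | floor below which a read is unmapped |

These are the end-to-end defaults of the quality-aware short-read
mappers this scoring emulates, so scores are directly comparable with
the -3 "review" guidance used for the verdict. Both strands are
searched (mate 2 of a paired library is reverse-complemented by
construction); ties prefer the forward strand, then the smaller
reference start, then fewer gap columns. Mates are aligned
independently: the metrics are defined per read, and a fragment-size
model would add nothing the verdict uses.

Two routes exist. `align_end_to_end` is the reference implementation:
exact affine-gap dynamic programming, global in the read and local in
the reference (leading/trailing reference gaps are free and never
emitted). `align_all` is the batch route: exact 20-mer seeds tiled
across the read anchor candidate diagonals; a gapless rescore of each
diagonal is accepted outright when its score is at least
`-(gap_open + gap_extend)` — no gapped alignment can beat that — and at
least `-(n_seeds * mismatch_min)`, the best any placement missed by
every seed could score. Otherwise a windowed DP (band 15 around the
top three anchored diagonals) rescues gapped placements, and a read
with no anchor at all falls back to the full exact DP. The within-row
affine-gap recurrence is solved with a prefix-max scan, which is valid
because an optimal path never leaves and re-enters a reference gap
without consuming a read base. The batch route is cross-checked
against the exact DP and against an independent placement-enumeration
oracle in the test suite.

## Connectivity

Coverage at position i counts reads placing a read base on i (deletion
columns do not count). Connectivity at i counts reads that place read
bases on i-1, i and i+1 *consecutively in the read* — no insertion or
deletion between them. Reads that start or end at i therefore never
support it, and neither do reads gapped across it; the two reference
ends are always 0. The gap-free requirement is what makes a single
indel at the junction detectable: every read spanning the junction of a
candidate with one extra (or missing) base must carry a gap column
there, so connectivity at the affected adjacency collapses to zero even
though coverage stays high. For gapless alignments the rule reduces to
the simpler "exclude reads that start or end here".

## Verdict

PASS requires (defaults on `Thresholds`):

* minimum connectivity >= 2 everywhere in the junction window
  `[junction_index - w + 1, junction_index + w]`, with `w` = read
  length - 1 so every adjacency a junction-spanning read could attest
  is examined. The floor of 2 guards against a single chimeric read
  fabricating support.
* minimum junction connectivity >= 25% of the profile-wide median
  connectivity. This relative criterion is what actually catches an
  indel absorbed inside a homopolymer: deleting (or duplicating) a base
  of a run near the junction leaves the few reads whose ends fall
  inside the run as the only gap-free support for the run's boundary
  adjacencies — roughly coverage x run-length / read-length reads, a
  number that grows with coverage and therefore clears any *absolute*
  floor once coverage is high, while always sitting far below the
  profile median. A scale-free threshold rejects it at any depth.
* average alignment score of mapped reads > -3.0. Scores of -3 or
  lower are additionally flagged for manual review regardless of the
  verdict, as is a junction connectivity below 25% of the median.

A FAIL is a scientific result, not an error: the CLI exits 0 either way.

## Permutation study

Each of the candidate's two 50-bp end windows is perturbed per base
with probability p (defaults 0.01 and 0.05), by deletion or by
insertion of a uniform random base after the sampled position; the
perturbed sequence is re-flipped and the whole mapping/verdict pipeline
re-run. The default design is 2 probabilities x 2 operations x 100
repetitions = 400 iterations plus one probability-0 baseline. Entries
are ranked by the Euclidean distance to the baseline in (similarity,
mean junction connectivity, average alignment score) space, each axis
standardized by the baseline's absolute value (or 1 when that is 0);
ties share the smaller rank.

Because the edit probability is per base, an iteration can draw zero
edits (probability 0.37 at p = 0.01 over 100 positions); such an entry
is byte-identical to the baseline and trivially passes, so pass counts
and the false-positive rate are computed over entries with at least one
edit, with zero-edit entries reported separately. Insertions are
essentially always caught (the inserted base is novel, so no read can
support its adjacencies). Deletions are the only source of false
positives: a single deletion inside a homopolymer can be absorbed by
reads whose ends fall inside the run, but every junction-spanning read
then carries a gap penalty, so any such pass shows a strictly worse
average score than the baseline — which is exactly why a poor score is
the recommended review trigger.

Per-iteration randomness comes from a substream seeded with (study
seed, iteration index), so any subset of iterations is reproducible.

## Synthetic data

`simdata` generates the study conditions end to end: an i.i.d. circular
genome of configurable length and GC; paired 2x100 bp reads whose
fragment starts are uniform on the circle (so reads wrap the origin —
the evidence the method lives on), mate 2 reverse-complemented,
substitution errors i.i.d. at `sub_rate`; and a scaffold built as
`random-flank + rotated-genome + first-dup_len-bases + random-flank`,
the canonical artifact structure of iterative baiting assemblers.
Reads are simulated from the true circle, not the scaffold.

Qualities are constant Q40 except erroneous bases, which default to Q8:
miscalled bases in real libraries carry low quality, and the
quality-scaled mismatch penalty presupposes it. At Q8 a substitution
costs 2, so a 1%-error 100-bp library averages about -2 — a sound
assembly — while putting errors at Q40 would cost 6 each and push even
a correct assembly to the review threshold, which no real quality-aware
pipeline exhibits. The generator does *not* model indel sequencing
errors (off by default), coverage bias, NUMT contamination or
platform-specific error profiles; passing tests therefore demonstrate
the method's behavior under clean wrap-around evidence, not robustness
to every real-data pathology.

## Problem sizes

The bundled studies use a 16 kb genome (GC 0.40) with 2x100 bp reads at
40x and substitution rate 0.005 for the recovery and permutation
experiments (scaffold: 300 bp duplicated end, 200 bp random flanks;
trim with k = 31, min_span = 10 kb), error-free 30x reads for the
single-indel sensitivity check, and a 2 kb / 2x50 bp / 20x fixture for
unit-scale tests. The permutation study in the test suite runs 25
repetitions per condition and the acceptance script 5, chosen as the
smallest designs in which the qualitative claims (no insertion or
5%-condition pass; deletion-only false positives with worse scores) are
stable.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; SAM's 1-based POS is
  converted at the boundary (pysam already does).
* FASTQ qualities are fixed Phred+33; no autodetection.
* `flip` of a sequence shorter than 2, composition of an all-N
  sequence, an empty read, or a perturbation window wider than half the
  circle raise typed errors rather than guessing.
* Reads longer than the reference are unmapped by definition.
* External SAM ingestion preserves the producer's AS:i scale as-is and
  records the provenance on each alignment; soft clips are accepted but
  contribute nothing to any metric, hard clips are rejected. Records
  with neither AS:i nor MD cannot be scored and are a format error.
* `base_composition` reports percentages over non-N bases, rounded to
  two decimals after computing GC = C% + G%.

## Known limitations

* One circular molecule per scaffold; multiple distinct circles or
  heteroplasmy are out of scope.
* Only same-strand k-mer duplicates are considered: circularity
  artifacts arise from the assembler walking past the origin on the
  same strand, whereas reverse-complement hits indicate inverted
  repeats.
* The seeded batch aligner can in principle miss a placement whose
  every seed is disrupted when another anchored placement exists; the
  exact-DP route is available (`exact=True`) where that matters.
* The verdict has no confidence interval; the permutation study is the
  calibration instrument.
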