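"""End-to-end alignment: scoring examples, oracle equivalence, fast path."""

import random
from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

import circinfer as ci
from circinfer.errors import DegenerateInputError
from circinfer.model import reverse_complement

LOOSE = ci.ScoringScheme(min_score=-(10 ** 6))


def rec(seq, quals=None, rid="r"):
    return ci.SeqRecord(rid, seq, quals if quals is not None
                        else [40] * len(seq))


def oracle_score(read, quals, ref, scheme):
    """Independent top-down scorer over (read position, ref position,
    previous op) states; both strands, like the implementation."""
    def one(read, quals):
        m, n = len(read), len(ref)

        @lru_cache(maxsize=None)
        def go(i, j, prev):
            if i == m:
                return 0
            best = -(10 ** 9)
            if j < n:
                a, b = read[i], ref[j]
                pen = scheme.n_penalty if "N" in (a, b) else (
                    0 if a == b else scheme.mismatch_penalty(quals[i]))
                best = max(best, go(i + 1, j + 1, "M") - pen)
            best = max(best, go(i + 1, j, "I") - scheme.gap_extend
                       - (scheme.gap_open if prev != "I" else 0))
            if j < n and i > 0:
                best = max(best, go(i, j + 1, "D") - scheme.gap_extend
                           - (scheme.gap_open if prev != "D" else 0))
            return best

        return max(go(0, s, "") for s in range(n + 1))

    return max(one(read, tuple(quals)),
               one(reverse_complement(read), tuple(reversed(quals))))


class TestScoringScheme:
    def test_quality_scaling_endpoints(self):
        s = ci.ScoringScheme()
        assert s.mismatch_penalty(0) == 2
        assert s.mismatch_penalty(40) == 6
        assert s.mismatch_penalty(60) == 6  # capped at 40

    def test_default_floor(self):
        assert ci.ScoringScheme().score_floor(100) == -61

    def test_invalid_penalties(self):
        with pytest.raises(ValueError):
            ci.ScoringScheme(mismatch_min=7, mismatch_max=6)


class TestAlignEndToEnd:
    def test_exact_substring_scores_zero(self):
        a = ci.align_end_to_end(rec("ACGT"), "TTACGTTT")
        assert (a.score, a.ref_start, a.columns) == (0, 2, "MMMM")

    def test_single_mismatch_quality_scaled(self):
        a = ci.align_end_to_end(rec("ACGT"), "TTACCTTT", LOOSE)
        assert a.score == -6            # 2 + floor(4 * 40/40)
        a = ci.align_end_to_end(rec("ACGT", [0] * 4), "TTACCTTT", LOOSE)
        assert a.score == -2            # quality 0

    def test_single_insertion(self):
        a = ci.align_end_to_end(rec("ACGGT"), "CCACGTCC", LOOSE)
        assert a.score == -8            # gap_open 5 + gap_extend 3
        assert a.columns.count("I") == 1

    def test_below_floor_is_unmapped(self):
        # one Q40 mismatch on a 4-mer: -6 < floor(-(0.6+0.6*4)) = -3
        a = ci.align_end_to_end(rec("ACGT"), "TTACCTTT")
        assert not a.mapped
        assert a.score == -6
        assert a.columns == ""

    def test_reverse_strand(self):
        read = rec(reverse_complement("ACGTAC"))
        a = ci.align_end_to_end(read, "TTACGTACTT")
        assert a.mapped and a.strand == "-" and a.score == 0
        assert (a.ref_start, a.ref_end) == (2, 8)

    def test_read_longer_than_reference(self):
        a = ci.align_end_to_end(rec("ACGTACGT"), "ACGT")
        assert not a.mapped

    def test_empty_read_is_degenerate(self):
        with pytest.raises(Exception):
            ci.align_end_to_end(ci.SeqRecord("r", ""), "ACGT")

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(data=st.data())
    def test_matches_enumeration_oracle(self, data):
        read = data.draw(st.text(alphabet="ACGTN", min_size=1, max_size=8))
        ref = data.draw(st.text(alphabet="ACGT", min_size=len(read),
                                max_size=20))
        quals = data.draw(st.lists(st.sampled_from([0, 11, 22, 40]),
                                   min_size=len(read), max_size=len(read)))
        got = ci.align_end_to_end(rec(read, quals), ref, LOOSE)
        assert got.score == oracle_score(read, quals, ref, LOOSE)
        assert got.score <= 0

    def test_mismatch_lowers_by_mismatch_max(self, rng):
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        read = ref[100:180]
        base = ci.align_end_to_end(rec(read), ref, LOOSE).score
        mutated = read[:40] + {"A": "C", "C": "A", "G": "T", "T": "G"}[read[40]] \
            + read[41:]
        worse = ci.align_end_to_end(rec(mutated), ref, LOOSE).score
        assert base == 0
        assert worse == base - ci.ScoringScheme().mismatch_max

    def test_rotation_shifts_ref_start(self, rng):
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, size=400))
        read = ref[200:260]
        rot = 50
        rotated = ref[rot:] + ref[:rot]
        a = ci.align_end_to_end(rec(read), ref)
        b = ci.align_end_to_end(rec(read), rotated)
        assert a.score == b.score == 0
        assert b.ref_start == a.ref_start - rot


class TestAlignAll:
    def test_empty_input(self):
        assert ci.align_all([], "ACGTACGT") == []

    def test_error_free_reads_score_zero(self, rng):
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, size=1000))
        reads = []
        for i in range(10):
            s = int(rng.integers(0, 900))
            seq = ref[s:s + 80]
            if i % 2:
                seq = reverse_complement(seq)
            reads.append(rec(seq, rid=f"r{i}"))
        alns = ci.align_all(reads, ref)
        assert all(a.mapped and a.score == 0 for a in alns)

    def test_deterministic(self, sim2k):
        flipped, _, _ = ci.flip(sim2k["genome"])
        a = ci.align_all(sim2k["reads"][:60], flipped)
        b = ci.align_all(sim2k["reads"][:60], flipped)
        assert a == b

    def test_fast_path_matches_exact_dp(self, rng):
        """Seeded/gapless batch route agrees with full DP on scores."""
        ref = "".join("ACGT"[b] for b in rng.integers(0, 4, size=3000))
        reads = []
        for i in range(40):
            s = int(rng.integers(0, 2900))
            seq = list(ref[s:s + 90])
            quals = [40] * 90
            for _ in range(int(rng.integers(0, 4))):  # up to 3 substitutions
                p = int(rng.integers(0, 90))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
                quals[p] = 20
            if int(rng.integers(0, 4)) == 0:          # occasional indel
                p = int(rng.integers(1, 89))
                if rng.integers(0, 2):
                    seq.insert(p, "ACGT"[int(rng.integers(0, 4))])
                    quals.insert(p, 40)
                else:
                    del seq[p], quals[p]
            s2 = "".join(seq)
            if i % 2:
                s2, quals = reverse_complement(s2), quals[::-1]
            reads.append(rec(s2, quals, rid=f"r{i}"))
        fast = ci.align_all(reads, ref)
        exact = ci.align_all(reads, ref, exact=True)
        for f, e in zip(fast, exact):
            assert f.mapped == e.mapped
            if f.mapped:
                assert f.score == e.score
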