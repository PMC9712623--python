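"""Sequence/motif primitives: alignment, projection, scanning, ti/tv."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepra.motifs import pwm_from_consensus
from tepra.seqcore import (
    AlignScoring,
    MotifModel,
    SequenceRecord,
    SubstitutionModel,
    estimate_titv,
    extract_reference_window,
    global_align,
    project_to_reference,
    reverse_complement,
    scan_motif,
)

# ---------------------------------------------------------------------------
# brute-force alignment oracle: enumerate every monotone alignment path


@lru_cache(maxsize=None)
def _paths(n: int, m: int) -> tuple:
    """All move sequences (D=diagonal, U=gap-in-query, L=gap-in-ref)."""
    if n == 0 and m == 0:
        return ("",)
    out = []
    if n > 0 and m > 0:
        out += [p + "D" for p in _paths(n - 1, m - 1)]
    if n > 0:
        out += [p + "U" for p in _paths(n - 1, m)]
    if m > 0:
        out += [p + "L" for p in _paths(n, m - 1)]
    return tuple(out)


def _score_path(path: str, ref: str, query: str, sc: AlignScoring) -> float:
    i = j = 0
    score = 0.0
    prev = ""
    for move in path:
        if move == "D":
            score += sc.match if ref[i] == query[j] else sc.mismatch
            i += 1
            j += 1
        else:
            score += sc.gap_extend if move == prev else sc.gap_open
            if move == "U":
                i += 1
            else:
                j += 1
        prev = move
    return score


def brute_force_best(ref: str, query: str, sc: AlignScoring) -> float:
    return max(_score_path(p, ref, query, sc) for p in _paths(len(ref), len(query)))


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.ref_row == "ACGT" and aln.query_row == "ACGT"
        assert aln.identity == 1.0
        assert "-" not in aln.ref_row + aln.query_row

    def test_single_gap_example(self):
        sc = AlignScoring(1, -1, -2, -0.5)
        aln = global_align("ACGT", "AGT", sc)
        cols = list(zip(aln.ref_row, aln.query_row))
        assert sum(q == "-" for _, q in cols) == 1
        assert sum(r == q for r, q in cols) == 3
        assert aln.score == brute_force_best("ACGT", "AGT", sc)

    def test_empty_query(self):
        aln = global_align("ACGT", "")
        assert aln.query_row == "----"
        assert aln.score == -2 + 3 * -0.5

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            global_align("", "ACGT")

    def test_invalid_character_named(self):
        with pytest.raises(ValueError, match="'X'"):
            global_align("ACGT", "ACXT")

    def test_round_trip(self, rng):
        for _ in range(50):
            ref = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 30)))
            query = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 30)))
            aln = global_align(ref, query)
            assert aln.ref_row.replace("-", "") == ref
            assert aln.query_row.replace("-", "") == query
            assert not any(
                r == q == "-" for r, q in zip(aln.ref_row, aln.query_row)
            )

    @given(
        ref=st.text(alphabet="ACGT", min_size=1, max_size=12),
        query=st.text(alphabet="ACGTN", min_size=0, max_size=12),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_round_trip_property(self, ref, query):
        """Ungapping either row of any alignment recovers the input."""
        aln = global_align(ref, query)
        assert aln.ref_row.replace("-", "") == ref
        assert aln.query_row.replace("-", "") == query

    def test_optimal_vs_bruteforce(self):
        """Alignment score equals exhaustive enumeration over all paths."""
        rng = np.random.default_rng(77)
        sc = AlignScoring(1, -1, -2, -0.5)
        for _ in range(300):
            n, m = rng.integers(1, 7), rng.integers(0, 7)
            ref = "".join(rng.choice(list("ACGT"), size=n))
            query = "".join(rng.choice(list("ACGT"), size=m))
            got = global_align(ref, query, sc).score
            assert got == pytest.approx(brute_force_best(ref, query, sc))


class TestProjection:
    def _aligned(self, ref, queries):
        return [global_align(ref, q) for q in queries]

    def test_identity_queries(self):
        m = project_to_reference(self._aligned("ACGTACGT", ["ACGTACGT", "ACGTACGT"]))
        assert m.ref_length == 8
        assert m.row(m.element_ids[0]) == "ACGTACGT"
        assert m.retained_mask.all()

    def test_insertion_dropped(self):
        ref = "ACGTACGTACGT"
        query = "ACGTAAAACGTACGT"  # 3-bp insertion
        m = project_to_reference([global_align(ref, query)])
        assert m.ref_length == len(ref)
        # inserted bases are absent: row length equals reference length
        assert len(m.row(m.element_ids[0])) == len(ref)

    def test_retained_mask_twenty_percent(self):
        # 10 elements; one trailing column covered by exactly 1 element
        ref = "ACGTACGTAC"
        short = "ACGTACGTA"  # lacks final base
        alns = [global_align(ref, short) for _ in range(9)] + [global_align(ref, ref)]
        for i, a in enumerate(alns):
            a.query_id = f"q{i}"
        m = project_to_reference(alns)
        assert not m.retained_mask[-1]  # 1/10 = 10% < 20%
        assert m.retained_mask[:-1].all()

    def test_order_invariance(self, rng):
        ref = "ACGTACGTACGTACGT"
        queries = ["ACGTACGTACGTACGT", "ACGTTCGTACGAACGT", "ACGTACG", "TCGTACGTACGTACGA"]
        alns = [global_align(ref, q) for q in queries]
        for i, a in enumerate(alns):
            a.query_id = f"q{i}"
        m1 = project_to_reference(alns)
        order = rng.permutation(len(alns))
        m2 = project_to_reference([alns[i] for i in order])
        assert m1.ref_length == m2.ref_length
        assert np.array_equal(m1.retained_mask, m2.retained_mask)

    def test_mismatched_reference_errors(self):
        a1 = global_align("ACGTACGT", "ACGTACGT")
        a2 = global_align("ACGTACGA", "ACGTACGA")
        with pytest.raises(ValueError, match="different reference"):
            project_to_reference([a1, a2])


class TestWindowExtraction:
    def test_identity_window(self):
        ref = "ACGT" * 50  # 200 bp
        aln = global_align(ref, ref)
        out = extract_reference_window([aln], (0, 160), min_len=70, max_len=160)
        assert out.fragments == [("query", ref[:160])]

    def test_too_short_excluded(self):
        ref = "ACGT" * 50
        query = ref[:40] + ref[150:]  # 110-bp deletion inside the window
        aln = global_align(ref, query)
        out = extract_reference_window([aln], (0, 160), min_len=70, max_len=160)
        assert out.excluded == {"query": "too_short"}

    def test_too_long_excluded(self):
        ref = "ACGT" * 50
        query = ref[:80] + "AA" + ref[80:]  # 2-bp insertion inside window
        aln = global_align(ref, query)
        out = extract_reference_window([aln], (0, 160), min_len=70, max_len=160)
        assert out.excluded == {"query": "too_long"}

    def test_forbidden_subsequence(self):
        ref = "ACGT" * 50
        out = extract_reference_window(
            [global_align(ref, ref)], (0, 160), 70, 160, ["CGTA"]
        )
        assert out.excluded == {"query": "forbidden_subsequence"}

    def test_window_out_of_range(self):
        aln = global_align("ACGT", "ACGT")
        with pytest.raises(ValueError, match="out of range"):
            extract_reference_window([aln], (0, 10))


class TestScanMotif:
    def test_consensus_hit(self):
        motif = pwm_from_consensus("m", "ACGTACGT", 0.95)
        seq = "TTTTT" + "ACGTACGT" + "TTTTT"
        hits = scan_motif(seq, motif, 1e-4)
        assert any(h.offset == 5 and h.strand == "+" for h in hits)

    def test_all_n_no_hits(self):
        motif = pwm_from_consensus("m", "ACGTACGT", 0.95)
        assert scan_motif("N" * 30, motif, 1.0) == []

    def test_p_one_counts_all_windows(self):
        motif = pwm_from_consensus("m", "ACGT", 0.9)
        seq = "ACGTACGTAC"  # L=10, k=4 -> 2*(10-4+1)=14
        assert len(scan_motif(seq, motif, 1.0)) == 14

    def test_short_sequence_empty(self):
        motif = pwm_from_consensus("m", "ACGTACGT", 0.9)
        assert scan_motif("ACG", motif, 1.0) == []

    def test_minus_strand_offset(self):
        motif = pwm_from_consensus("m", "AACGTCAG", 0.97)
        rc = reverse_complement("AACGTCAG")
        seq = "GGGGG" + rc + "GGGGG"
        hits = scan_motif(seq, motif, 1e-4)
        assert any(h.offset == 5 and h.strand == "-" for h in hits)

    def test_hit_rate_calibration(self):
        """On iid uniform sequence the per-window hit rate tracks p."""
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(4) * 2, size=10)
        motif = MotifModel("random", probs)
        p = 0.01
        n_windows = 10**6
        seq = "".join(rng.choice(list("ACGT"), size=n_windows + motif.k - 1))
        hits = scan_motif(seq, motif, p, both_strands=False)
        rate = len(hits) / n_windows
        se = np.sqrt(p * (1 - p) / n_windows)
        assert abs(rate - p) < 3 * se

    def test_threshold_p_bounds(self):
        motif = pwm_from_consensus("m", "ACGTAC", 0.9)
        with pytest.raises(ValueError):
            motif.threshold_for_p(0.0)
        with pytest.raises(ValueError):
            motif.threshold_for_p(1.5)


class TestTiTv:
    def _matrix(self, ref, rows):
        alns = [global_align(ref, r) for r in rows]
        for i, a in enumerate(alns):
            a.query_id = f"q{i}"
        return project_to_reference(alns)

    def test_identity_zero_rates(self):
        m = self._matrix("ACGTACGT", ["ACGTACGT"])
        sub = estimate_titv(m)
        assert sub.s_transition == 0 and sub.s_transversion == 0

    def test_single_transition(self):
        m = self._matrix("ACGT", ["GCGT"])  # A->G transition
        sub = estimate_titv(m)
        assert sub.s_transition == 0.25
        assert sub.s_transversion == 0.0

    def test_all_transversions(self):
        m = self._matrix("ACGT", ["TGCA"])
        sub = estimate_titv(m)
        assert sub.s_transversion == 1.0
        assert sub.s_transition == 0.0

    def test_rates_sum_to_mismatch_fraction(self, rng):
        bases = list("ACGT")
        ref = "".join(rng.choice(bases, size=60))
        rows = []
        for _ in range(5):
            row = [
                rng.choice(bases) if rng.random() < 0.3 else b for b in ref
            ]
            rows.append("".join(row))
        m = self._matrix(ref, rows)
        sub = estimate_titv(m)
        # mismatch fraction over positions where both reference and element
        # carry a real base (the same universe the estimator uses)
        ref_arr = np.array(list(ref))
        n_mismatch = n_aligned = 0
        for e in m.element_ids:
            row = np.array(list(m.row(e)))
            both = np.isin(row, list("ACGT"))
            n_aligned += both.sum()
            n_mismatch += (row[both] != ref_arr[both]).sum()
        assert sub.s_transition + sub.s_transversion == pytest.approx(
            n_mismatch / n_aligned
        )

    def test_pooling_over_subset(self):
        m = self._matrix("ACGT", ["GCGT", "ACGT"])
        sub = estimate_titv(m)  # 1 transition over 8 aligned bases
        assert sub.s_transition == pytest.approx(1 / 8)

    def test_zero_aligned_errors(self):
        with pytest.raises(ValueError):
            estimate_titv(self._matrix("ACGT", ["NNNN"]))


class TestSubstitutionModel:
    def test_step_matrix_rows_sum_to_one(self):
        P = SubstitutionModel("s", 0.1, 0.06).step_matrix()
        assert np.allclose(P.sum(axis=1), 1.0)
        assert P[0, 2] == 0.1  # A->G transition
        assert P[0, 1] == 0.03  # A->C specific transversion

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            SubstitutionModel("s", 0.7, 0.5)


def test_sequence_record_validation():
    with pytest.raises(ValueError, match="role"):
        SequenceRecord("x", "human", "ACGT", role="nonsense")
    with pytest.raises(ValueError, match="empty"):
        SequenceRecord("x", "human", "", role="present_day")
    with pytest.raises(ValueError):
        SequenceRecord("x", "human", "ACGT", coords=("chr1", 0, 3, "+"))
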