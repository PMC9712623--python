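"""Window conservation tests and the neutral motif-retention model."""

import itertools

import numpy as np
import pytest

from tepra.conservation import (
    expected_motif_conservation,
    observed_motif_conservation,
    proportion_test,
    shared_conserved_windows,
    simulate_motif_conservation,
    window_conservation,
)
from tepra.motifs import pwm_from_consensus
from tepra.seqcore import (
    ReferenceAlignmentMatrix,
    SubstitutionModel,
    encode,
    scan_motif,
)


def brute_force_expected(anc, motif, sub, p_threshold):
    """Independent oracle: enumerate all 4^k k-mers, score via scan_motif,
    multiply single-step substitution probabilities by hand."""
    k = motif.k
    P = {
        ("stay",): 1 - sub.s_transition - sub.s_transversion,
    }
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    total = 0.0
    for kmer in map("".join, itertools.product("ACGT", repeat=k)):
        if not scan_motif(kmer, motif, p_threshold):
            continue
        p = 1.0
        for a, b in zip(anc, kmer):
            if a == b:
                p *= 1 - sub.s_transition - sub.s_transversion
            elif transitions[a] == b:
                p *= sub.s_transition
            else:
                p *= sub.s_transversion / 2
        total += p
    return total


def matrix_from_rows(ref: str, rows: dict[str, str]) -> ReferenceAlignmentMatrix:
    data = np.vstack([encode(r) for r in rows.values()])
    return ReferenceAlignmentMatrix(ref_id="ref", ref_seq=ref, element_ids=list(rows), data=data)


class TestExpected:
    def test_zero_rates_gives_one(self):
        # k = 7 so that the consensus itself attains p <= 1e-4 (0.25^7)
        motif = pwm_from_consensus("m", "ACGTACG", 0.9)
        sub = SubstitutionModel("s", 0.0, 0.0)
        assert expected_motif_conservation(motif.consensus, motif, sub) == pytest.approx(1.0)

    def test_single_kmer_matching_set_closed_form(self):
        # sharp PWM + threshold at the maximal score: the matching set is the
        # consensus plus (both strands are scanned) its reverse complement,
        # so retention = stay^k + P(anc -> revcomp(anc))
        motif = pwm_from_consensus("m", "ACGG", 0.97)
        p_at_max = 0.25**4  # probability the background attains the max score
        sub = SubstitutionModel("s", 0.06, 0.04)  # stay = 0.9
        got = expected_motif_conservation("ACGG", motif, sub, p_threshold=p_at_max * 1.001)
        # ACGG -> CCGT: A->C and G->T are specific transversions (0.02 each)
        p_rc = 0.02 * 0.9 * 0.9 * 0.02
        assert got == pytest.approx(0.9**4 + p_rc, abs=1e-12)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(8)
        sub = SubstitutionModel("s", 0.05, 0.03)
        for k in (4, 5, 6):
            probs = rng.dirichlet(np.ones(4), size=k)
            from tepra.seqcore import MotifModel

            motif = MotifModel(f"r{k}", probs)
            anc = "".join(rng.choice(list("ACGT"), size=k))
            exact = expected_motif_conservation(anc, motif, sub, 1e-2)
            brute = brute_force_expected(anc, motif, sub, 1e-2)
            assert exact == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_rates_single_kmer(self):
        motif = pwm_from_consensus("m", "ACGG", 0.97)
        p_at_max = 0.25**4 * 1.001
        prev = None
        for s in [0.0, 0.02, 0.05, 0.1, 0.2]:
            val = expected_motif_conservation(
                "ACGG", motif, SubstitutionModel("s", s, s / 2), p_at_max
            )
            if prev is not None:
                assert val <= prev + 1e-12
            prev = val

    def test_bad_ancestral_length(self):
        motif = pwm_from_consensus("m", "ACGG", 0.9)
        with pytest.raises(ValueError):
            expected_motif_conservation("ACGGT", motif, SubstitutionModel("s", 0, 0))


class TestSimulated:
    def test_zero_rates_fixed_fraction(self):
        motif = pwm_from_consensus("m", "ACGTACG", 0.95)
        sub = SubstitutionModel("s", 0.0, 0.0)
        sims = simulate_motif_conservation([motif.consensus] * 20, motif, sub, 100, seed=4)
        assert np.all(sims == 1.0)

    def test_deterministic(self):
        motif = pwm_from_consensus("m", "ACGTACG", 0.95)
        sub = SubstitutionModel("s", 0.05, 0.02)
        s1 = simulate_motif_conservation([motif.consensus] * 10, motif, sub, 200, seed=9)
        s2 = simulate_motif_conservation([motif.consensus] * 10, motif, sub, 200, seed=9)
        assert np.array_equal(s1, s2)

    def test_monte_carlo_matches_exact(self):
        """Mean simulated retention agrees with the exact expectation."""
        motif = pwm_from_consensus("m", "ACGTAC", 0.92)
        sub = SubstitutionModel("s", 0.06, 0.03)
        exact = expected_motif_conservation(motif.consensus, motif, sub, 1e-3)
        sims = simulate_motif_conservation(
            [motif.consensus] * 50, motif, sub, 1000, seed=12, p_threshold=1e-3
        )
        se = np.sqrt(exact * (1 - exact) / (1000 * 50))
        assert abs(sims.mean() - exact) < 3 * se * 50**0.5  # per-sim SE, 1000 sims

    def test_unbiased_across_configurations(self):
        """Simulated retention is an unbiased estimator of the average
        exact retention probability (paired over 50 configurations)."""
        rng = np.random.default_rng(21)
        diffs = []
        for _ in range(50):
            k = int(rng.integers(4, 7))
            conf = float(rng.uniform(0.8, 0.97))
            motif = pwm_from_consensus("m", "".join(rng.choice(list("ACGT"), size=k)), conf)
            sub = SubstitutionModel("s", float(rng.uniform(0, 0.1)), float(rng.uniform(0, 0.06)))
            starts = ["".join(rng.choice(list("ACGT"), size=k)) if rng.random() < 0.3 else motif.consensus for _ in range(10)]
            exact = np.mean(
                [expected_motif_conservation(s, motif, sub, 1e-2) for s in starts]
            )
            sims = simulate_motif_conservation(starts, motif, sub, 200, seed=int(rng.integers(2**31)), p_threshold=1e-2)
            diffs.append(sims.mean() - exact)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-4

    def test_empty_elements_error(self):
        motif = pwm_from_consensus("m", "ACGT", 0.9)
        with pytest.raises(ValueError):
            simulate_motif_conservation([], motif, SubstitutionModel("s", 0, 0))


class TestWindows:
    def test_identical_elements_not_significant(self):
        ref = "ACGTACGTACGTACGTACGT"
        m = matrix_from_rows(ref, {f"e{i}": ref for i in range(6)})
        df = window_conservation(m)
        assert (df["p_raw"] == 1.0).all()
        assert not df["significant"].any()

    def test_gapped_element_excluded_from_window(self):
        ref = "ACGTACGTACGTACGTACGT"
        gapped = "-----" + ref[5:]
        m = matrix_from_rows(ref, {"g": gapped, "a": ref, "b": ref})
        df = window_conservation(m, max_excluded=5)
        first = df.iloc[0]
        assert first["n_elements"] == 2  # element with 5 gaps dropped

    def test_bonferroni_capped_at_one(self):
        ref = "ACGTACGTACGTACGTACGT"
        m = matrix_from_rows(ref, {f"e{i}": ref for i in range(4)})
        df = window_conservation(m)
        assert (df["p_bonferroni"] <= 1.0).all()

    def test_short_consensus_errors(self):
        m = matrix_from_rows("ACGTA", {"e": "ACGTA"})
        with pytest.raises(ValueError):
            window_conservation(m, width=10)

    def test_specificity_under_uniform_substitution(self):
        """Uniform-rate matrices yield few Bonferroni-significant windows."""
        rng = np.random.default_rng(31)
        n_sig = n_windows = 0
        for _ in range(30):
            ref = "".join(rng.choice(list("ACGT"), size=120))
            rows = {
                f"e{i}": "".join(
                    rng.choice(list("ACGT")) if rng.random() < 0.1 else b for b in ref
                )
                for i in range(25)
            }
            df = window_conservation(matrix_from_rows(ref, rows))
            n_sig += int(df["significant"].sum())
            n_windows += len(df)
        assert n_sig / n_windows <= 0.05


class TestSharedWindows:
    def _df(self, starts_sig, all_starts=range(0, 20)):
        import pandas as pd

        return pd.DataFrame(
            {
                "window_start": list(all_starts),
                "significant": [s in starts_sig for s in all_starts],
            }
        )

    def test_intersection(self):
        per = {
            "s1": self._df({3, 5}),
            "s2": self._df({3, 7}),
            "s3": self._df({3, 5, 7}),
        }
        out = shared_conserved_windows(per)
        assert out["window_starts"] == {3}

    def test_missing_in_one_species_excluded(self):
        per = {f"s{i}": self._df({4}) for i in range(6)}
        per["s6"] = self._df(set())
        assert shared_conserved_windows(per)["window_starts"] == set()

    def test_empty_input(self):
        assert shared_conserved_windows({})["window_starts"] == set()

    def test_motif_inside_merged_windows(self):
        consensus = "T" * 5 + "GCTGAGTCATG" + "T" * 5
        motif = pwm_from_consensus("JUN_like", "GCTGAGTCATG", 0.9)
        per = {"s1": self._df(set(range(0, 12)), range(0, 12))}
        out = shared_conserved_windows(per, consensus, [motif])
        names = {n for n, _, _ in out["motifs_inside"]}
        assert "JUN_like" in names


class TestObserved:
    def test_all_identical(self):
        ref = "TTTTTGCTGAGTCATGTTTTT"
        motif = pwm_from_consensus("m", "GCTGAGTCATG", 0.9)
        m = matrix_from_rows(ref, {f"e{i}": ref for i in range(5)})
        frac, n = observed_motif_conservation(m, (5, 16), motif)
        assert frac == 1.0 and n == 5

    def test_gapped_excluded(self):
        ref = "TTTTTGCTGAGTCATGTTTTT"
        motif = pwm_from_consensus("m", "GCTGAGTCATG", 0.9)
        gapped = ref[:8] + "-" + ref[9:]
        m = matrix_from_rows(ref, {"a": ref, "g": gapped})
        frac, n = observed_motif_conservation(m, (5, 16), motif)
        assert n == 1

    def test_no_retention(self):
        ref = "TTTTTGCTGAGTCATGTTTTT"
        motif = pwm_from_consensus("m", "GCTGAGTCATG", 0.95)
        lost = ref[:5] + "AAAAAAAAAAA" + ref[16:]
        m = matrix_from_rows(ref, {"a": lost})
        frac, n = observed_motif_conservation(m, (5, 16), motif)
        assert frac == 0.0

    def test_all_gapped_errors(self):
        ref = "TTTTTGCTGAGTCATGTTTTT"
        motif = pwm_from_consensus("m", "GCTGAGTCATG", 0.9)
        gapped = ref[:6] + "-" * 5 + ref[11:]
        m = matrix_from_rows(ref, {"g": gapped})
        with pytest.raises(ValueError):
            observed_motif_conservation(m, (5, 16), motif)


class TestProportionTest:
    def test_null(self):
        assert proportion_test(0.4, 0.4, 100) == pytest.approx(1.0)

    def test_known_z(self):
        # z = (0.693-0.448)/sqrt(0.448*0.552/100) = 4.926...
        from scipy.stats import norm

        z = (0.693 - 0.448) / np.sqrt(0.448 * 0.552 / 100)
        expected = 2 * norm.sf(abs(z))
        assert proportion_test(0.693, 0.448, 100) == pytest.approx(expected)
        assert proportion_test(0.693, 0.448, 100) < 0.05

    def test_errors(self):
        with pytest.raises(ValueError):
            proportion_test(0.5, 0.5, 0)
        with pytest.raises(ValueError):
            proportion_test(0.5, 1.0, 10)
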