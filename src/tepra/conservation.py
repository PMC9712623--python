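"""Conservation statistics and the neutral motif-retention model.

Two complementary questions are answered here.  First, which 10-bp windows
of the subfamily consensus are more conserved across copies than the
subfamily average (sliding-window t-tests, Bonferroni-corrected)?  Second,
are specific TF motifs retained more often than a neutral substitution
model predicts?  The neutral expectation sums, over every k-mer that still
passes the motif scanner's threshold, the probability of reaching that
k-mer from the ancestral k-mer under independent per-site transition/
transversion probabilities; the same model drives Monte-Carlo simulations,
and a one-sample proportion z-test compares observed retention with the
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import (
    A,
    C,
    G,
    GAP,
    N,
    T,
    MotifModel,
    ReferenceAlignmentMatrix,
    SubstitutionModel,
    decode,
    encode,
    scan_motif,
)


def window_conservation(
    matrix: ReferenceAlignmentMatrix,
    species: str = "",
    width: int = 10,
    step: int = 1,
    max_excluded: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sliding-window percent match to the consensus, tested per window.

    Per element and window, conservation = matches / compared positions,
    where gaps and N on either side are excluded; an element is dropped
    from a window when it has ``max_excluded`` or more excluded positions
    there.  Each window's element values are compared against the pooled
    values of all windows with a one-sided (greater) Welch t-test and
    Bonferroni correction over windows.  Zero-variance (degenerate) windows
    report p = 1.
    """
    L = matrix.ref_length
    if L < width:
        raise ValueError("consensus shorter than window width")
    ref = encode(matrix.ref_seq)
    el = matrix.data
    comparable = (el < N) & (ref[None, :] < N)
    match = comparable & (el == ref[None, :])

    # sliding sums via cumulative sums along positions
    def windowed(x: np.ndarray) -> np.ndarray:
        cs = np.cumsum(x, axis=1, dtype=np.int64)
        cs = np.concatenate([np.zeros((x.shape[0], 1), dtype=np.int64), cs], axis=1)
        return cs[:, width:] - cs[:, :-width]

    comp_w = windowed(comparable)[:, ::step]
    match_w = windowed(match)[:, ::step]
    excluded_w = width - comp_w
    valid = excluded_w < max_excluded
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(valid, match_w / np.maximum(comp_w, 1), np.nan)

    pooled = cons[~np.isnan(cons)]
    starts = np.arange(0, L - width + 1, step)
    rows = []
    for j, start in enumerate(starts):
        vals = cons[:, j]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2 or np.std(vals) == 0 or np.std(pooled) == 0:
            t_stat, p_raw = float("nan"), 1.0
        else:
            res = stats.ttest_ind(vals, pooled, equal_var=False, alternative="greater")
            t_stat, p_raw = float(res.statistic), float(res.pvalue)
            if np.isnan(p_raw):
                p_raw = 1.0
        rows.append((int(start), species, len(vals), float(np.mean(vals)) if len(vals) else float("nan"), t_stat, p_raw))
    df = pd.DataFrame(
        rows, columns=["window_start", "species", "n_elements", "mean", "t_statistic", "p_raw"]
    )
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * len(df))
    df["significant"] = df["p_bonferroni"] < alpha
    return df


def shared_conserved_windows(
    per_species: dict[str, pd.DataFrame],
    consensus: str | None = None,
    motifs: list[MotifModel] | None = None,
    p_threshold: float = 1e-4,
) -> dict:
    """Windows significantly conserved in every species, plus motifs inside.

    Returns the shared window starts, the merged intervals they cover on
    the consensus, and (if a consensus and motifs are given) the motif hits
    whose span lies fully inside a merged conserved interval.
    """
    if not per_species:
        return {"window_starts": set(), "intervals": [], "motifs_inside": []}
    sig_sets = [
        set(df.loc[df["significant"], "window_start"]) for df in per_species.values()
    ]
    shared = set.intersection(*sig_sets)
    width = 10
    intervals: list[tuple[int, int]] = []
    for s in sorted(shared):
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], s + width))
        else:
            intervals.append((s, s + width))
    motifs_inside = []
    if consensus and motifs:
        for motif in motifs:
            for hit in scan_motif(consensus, motif, p_threshold):
                span = (hit.offset, hit.offset + motif.k)
                if any(lo <= span[0] and span[1] <= hi for lo, hi in intervals):
                    motifs_inside.append((motif.name, span, hit.strand))
    return {"window_starts": shared, "intervals": intervals, "motifs_inside": motifs_inside}


# ---------------------------------------------------------------------------
# Neutral motif retention


def _matching_kmer_mask(motif: MotifModel, p_threshold: float) -> np.ndarray:
    """Boolean over all 4^k k-mers: does the k-mer (either strand) hit?

    k-mer index is base-4 with the first motif position most significant.
    """
    k = motif.k
    rc_scores = motif._int_scores[::-1, ::-1]  # reverse-complement PWM scores
    fwd = np.zeros(1, dtype=np.int64)
    rc = np.zeros(1, dtype=np.int64)
    for i in range(k):
        fwd = (fwd[:, None] + motif._int_scores[i][None, :]).ravel()
        rc = (rc[:, None] + rc_scores[i][None, :]).ravel()
    _, t_int = motif.threshold_for_p(p_threshold)
    return (fwd >= t_int) | (rc >= t_int)


def expected_motif_conservation(
    ancestral_motif_seq: str,
    motif: MotifModel,
    sub: SubstitutionModel,
    p_threshold: float = 1e-4,
) -> float:
    """Exact neutral retention probability from an ancestral k-mer.

    Sums, over all k-mers m that pass the scanner threshold, the product
    over positions of the single-step substitution probability from the
    ancestral base to m's base (stay = 1 - s_t - s_v; transition = s_t;
    each transversion = s_v / 2).
    """
    anc = encode(ancestral_motif_seq)
    if len(anc) != motif.k:
        raise ValueError("ancestral sequence length must equal motif width")
    if np.any(anc >= N):
        raise ValueError("ancestral k-mer must be gap- and N-free")
    P = sub.step_matrix()
    probs = np.ones(1)
    for i in range(motif.k):
        probs = (probs[:, None] * P[anc[i]][None, :]).ravel()
    mask = _matching_kmer_mask(motif, p_threshold)
    return float(probs[mask].sum())


def simulate_motif_conservation(
    element_motif_seqs: list[str],
    motif: MotifModel,
    sub: SubstitutionModel,
    n_sims: int = 1000,
    seed: int = 0,
    p_threshold: float = 1e-4,
) -> np.ndarray:
    """Monte-Carlo neutral retention fractions.

    Each simulation independently mutates every site of every element's
    motif region under the substitution model and records the fraction of
    elements whose mutated region still hits the motif (either strand).
    """
    if not element_motif_seqs:
        raise ValueError("empty element set")
    codes = np.stack([encode(s) for s in element_motif_seqs])
    if np.any(codes >= N):
        raise ValueError("motif regions must be gap- and N-free")
    n_el, k = codes.shape
    if k != motif.k:
        raise ValueError("motif region length must equal motif width")
    rng = np.random.default_rng(seed)
    ti_map = np.array([G, T, A, C], dtype=np.int8)
    tv1 = np.array([C, A, C, A], dtype=np.int8)
    tv2 = np.array([T, G, T, G], dtype=np.int8)

    u = rng.random((n_sims, n_el, k))
    coin = rng.random((n_sims, n_el, k)) < 0.5
    base = np.broadcast_to(codes, (n_sims, n_el, k)).copy()
    st, sv = sub.s_transition, sub.s_transversion
    is_ti = u < st
    is_tv = (u >= st) & (u < st + sv)
    base[is_ti] = ti_map[base[is_ti]]
    sel1 = is_tv & coin
    sel2 = is_tv & ~coin
    base[sel1] = tv1[base[sel1]]
    base[sel2] = tv2[base[sel2]]

    fwd_lut = motif._int_scores  # (k, 4)
    rc_lut = fwd_lut[::-1, ::-1]
    idx = np.arange(k)
    fwd_scores = fwd_lut[idx, base].sum(axis=2)
    rc_scores = rc_lut[idx, base].sum(axis=2)
    _, t_int = motif.threshold_for_p(p_threshold)
    retained = (fwd_scores >= t_int) | (rc_scores >= t_int)
    return retained.mean(axis=1)


def observed_motif_conservation(
    matrix: ReferenceAlignmentMatrix,
    span: tuple[int, int],
    motif: MotifModel,
    p_threshold: float = 1e-4,
) -> tuple[float, int]:
    """Fraction of elements retaining a motif at a reference span.

    Elements with a gap or N anywhere in the span are excluded from the
    denominator; retention means the scanner hits the element's projected
    bases within the span (either strand).
    """
    start, end = span
    if not (0 <= start < end <= matrix.ref_length):
        raise ValueError("span outside reference")
    region = matrix.data[:, start:end]
    eligible = np.all(region < N, axis=1)
    if not eligible.any():
        raise ValueError("all elements gapped or degenerate in span")
    retained = 0
    for row in region[eligible]:
        if scan_motif(decode(row), motif, p_threshold):
            retained += 1
    n = int(eligible.sum())
    return retained / n, n


def proportion_test(observed_fraction: float, expected_p: float, n: int) -> float:
    """Two-sided one-sample z-test of an observed proportion vs expectation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < expected_p < 1):
        raise ValueError("expected_p must be strictly inside (0, 1)")
    z = (observed_fraction - expected_p) / np.sqrt(expected_p * (1 - expected_p) / n)
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class MotifConservationReport:
    motif: str
    species: str
    reference_kind: str  # consensus_ancestral | human_ortholog
    expected_p: float
    observed_fraction: float
    n_elements: int
    sim_fractions: np.ndarray
    prop_test_p: float
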