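"""Position-wise association of sequence variation with enhancer activity.

TE-WAS treats the aligned copies of a TE subfamily like a GWAS cohort: at
every retained reference position the modal (major) base defines carriers
vs non-carriers, and a two-sided Fisher's exact test asks whether carrier
status co-occurs with the active/inactive MPRA label.  Motif-level follow-up
asks whether significant positions concentrate information content inside
known motif placements, against a null of uniformly shuffled significant
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import N, MotifModel, ReferenceAlignmentMatrix

_REL_TOL = 1.0 + 1e-7


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a,b],[c,d]].

    Exact hypergeometric summation: all tables with the observed margins
    whose probability does not exceed the observed table's (with a small
    relative tolerance, as in R's fisher.test).
    """
    row1, col1, total = a + b, a + c, a + b + c + d
    if total == 0:
        return 1.0
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))


def fisher_pvalue_lookup(total: int, row1: int, col1: int) -> dict[int, float]:
    """p-value for every attainable count a given fixed margins.

    Used to amortize the exact test across permutations that share margins.
    """
    if total == 0:
        return {0: 1.0}
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    return {
        int(a): float(min(1.0, pmf[pmf <= pa * _REL_TOL].sum()))
        for a, pa in zip(support, pmf)
    }


@dataclass
class AssociationResult:
    ref_position: int
    major_allele: str
    table: tuple[int, int, int, int]  # active-carrier, active-non, inactive-carrier, inactive-non
    p_value: float
    significant: bool
    tie_broken: bool = False


def associate_positions(
    matrix: ReferenceAlignmentMatrix,
    labels: "pd.Series | dict[str, bool]",
    alpha: float = 5e-5,
) -> list[AssociationResult]:
    """Per-position carrier-vs-activity Fisher scan over retained columns.

    The tested allele at each position is the most common A/C/G/T there;
    elements carrying any other base are non-carriers; gaps and N are
    treated as missing.  Monomorphic columns are excluded.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    ids = [e for e in matrix.element_ids if e in labels.index]
    if not ids:
        raise ValueError("no labelled elements in matrix")
    lab = labels.loc[ids].astype(bool).to_numpy()
    if lab.all() or not lab.any():
        raise ValueError("need at least one active and one inactive element")
    rows = np.array([matrix.element_ids.index(e) for e in ids])
    data = matrix.data[rows]

    results: list[AssociationResult] = []
    for col in np.flatnonzero(matrix.retained_mask):
        bases = data[:, col]
        usable = bases < N
        if usable.sum() == 0:
            continue
        counts = np.bincount(bases[usable], minlength=4)[:4]
        top = counts.max()
        major = int(np.flatnonzero(counts == top)[0])  # alphabetical tie-break
        tie = int((counts == top).sum()) > 1
        carrier = usable & (bases == major)
        noncarrier = usable & (bases != major)
        if noncarrier.sum() == 0:
            continue  # monomorphic
        a = int((carrier & lab).sum())
        b = int((noncarrier & lab).sum())
        c = int((carrier & ~lab).sum())
        d = int((noncarrier & ~lab).sum())
        p = fisher_two_sided(a, b, c, d)
        results.append(
            AssociationResult(
                int(col), "ACGT"[major], (a, b, c, d), p, p < alpha, tie
            )
        )
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [r.ref_position for r in results],
            "major_allele": [r.major_allele for r in results],
            "active_carrier": [r.table[0] for r in results],
            "active_noncarrier": [r.table[1] for r in results],
            "inactive_carrier": [r.table[2] for r in results],
            "inactive_noncarrier": [r.table[3] for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def permutation_calibration(
    matrix: ReferenceAlignmentMatrix,
    labels: "pd.Series | dict[str, bool]",
    n_permutations: int = 500,
    seed: int = 0,
    p_cut: float = 0.05,
) -> float:
    """Fraction of (position, permutation) tests with p < p_cut under
    label permutation.

    Shares the exact-test machinery of :func:`associate_positions` but
    amortizes the hypergeometric summation across permutations (per column,
    the carrier margin is fixed; only the active margin and the carrier-
    active count vary), so hundreds of permutations are cheap.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    ids = [e for e in matrix.element_ids if e in labels.index]
    lab = labels.loc[ids].astype(bool).to_numpy()
    rows = np.array([matrix.element_ids.index(e) for e in ids])
    data = matrix.data[rows]
    rng = np.random.default_rng(seed)

    columns = []  # (usable mask, carrier mask)
    for col in np.flatnonzero(matrix.retained_mask):
        bases = data[:, col]
        usable = bases < N
        if usable.sum() == 0:
            continue
        counts = np.bincount(bases[usable], minlength=4)[:4]
        major = int(np.flatnonzero(counts == counts.max())[0])
        carrier = usable & (bases == major)
        if (usable & ~carrier).sum() == 0:
            continue
        columns.append((usable, carrier))

    cache: dict[tuple[int, int, int], dict[int, float]] = {}
    n_sig = 0
    n_tests = 0
    for _ in range(n_permutations):
        perm = rng.permutation(lab)
        for usable, carrier in columns:
            total = int(usable.sum())
            row1 = int(perm[usable].sum())
            col1 = int(carrier.sum())
            key = (total, row1, col1)
            if key not in cache:
                cache[key] = fisher_pvalue_lookup(total, row1, col1)
            a = int((carrier & perm).sum())
            n_tests += 1
            n_sig += cache[key][a] < p_cut
    return n_sig / n_tests


@dataclass
class MotifICResult:
    motif: str
    span: tuple[int, int]
    n_sig_in_motif: int
    observed_ic_sum: float
    null_ic_sums: np.ndarray
    p_value: float
    reported: bool


def motif_ic_overrepresentation(
    sig_positions: set[int],
    motifs: list[tuple[MotifModel, tuple[int, int]]],
    tested_positions: set[int],
    n_shuffles: int = 1000,
    min_sig_in_motif: int = 2,
    seed: int = 0,
) -> list[MotifICResult]:
    """Do significant positions carry unusually high motif information?

    The observed statistic is the summed per-position IC (2 + sum p log2 p,
    uniform background) of significant positions inside the motif span.  The
    null redraws |sig| positions uniformly from the tested set 1000 times; a
    motif is reported when a one-sided t-test places the observed sum above
    the null (p < 0.05) and at least ``min_sig_in_motif`` significant
    positions fall inside the span.
    """
    import warnings

    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives an unstable null", stacklevel=2)
    if not sig_positions <= tested_positions:
        raise ValueError("sig_positions must be a subset of tested_positions")
    rng = np.random.default_rng(seed)
    tested = np.array(sorted(tested_positions))
    n_sig = len(sig_positions)
    shuffles = np.stack(
        [rng.choice(tested, size=n_sig, replace=False) for _ in range(n_shuffles)]
    ) if n_sig else np.zeros((n_shuffles, 0), dtype=int)

    results = []
    for motif, (start, end) in motifs:
        if end - start != motif.k:
            raise ValueError(f"span {start}-{end} does not match motif width {motif.k}")
        ic_positions = np.arange(start, end)
        ic_vals = motif.information_content()
        lookup = dict(zip(ic_positions, ic_vals))
        observed = sum(lookup.get(p, 0.0) for p in sig_positions)
        n_in = sum(1 for p in sig_positions if start <= p < end)
        null = np.array(
            [sum(lookup.get(int(p), 0.0) for p in row) for row in shuffles]
        )
        if null.std(ddof=1) == 0:
            p_value = 1.0 if observed <= null.mean() else 0.0
        else:
            p_value = float(
                stats.ttest_1samp(null, popmean=observed, alternative="less").pvalue
            )
        reported = p_value < 0.05 and n_in >= min_sig_in_motif
        results.append(
            MotifICResult(motif.name, (start, end), n_in, observed, null, p_value, reported)
        )
    return results


def motif_presence_enrichment(
    active_ids: list[str],
    inactive_ids: list[str],
    motif_hits: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif Fisher test of hit presence in active vs inactive elements.

    Bonferroni correction over the motifs actually tested; motifs absent
    from every element are skipped.
    """
    if not active_ids or not inactive_ids:
        raise ValueError("both groups must be non-empty")
    motifs = sorted({m for hits in motif_hits.values() for m in hits})
    rows = []
    for m in motifs:
        a = sum(1 for e in active_ids if m in motif_hits.get(e, set()))
        c = sum(1 for e in inactive_ids if m in motif_hits.get(e, set()))
        if a + c == 0:
            continue
        b, d = len(active_ids) - a, len(inactive_ids) - c
        p = fisher_two_sided(a, b, c, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c else float("inf")
        rows.append((m, a, b, c, d, odds, p))
    df = pd.DataFrame(
        rows,
        columns=["motif", "active_hit", "active_nohit", "inactive_hit", "inactive_nohit", "odds_ratio", "p_value"],
    )
    n_tested = len(df)
    df["p_adjusted"] = np.minimum(1.0, df["p_value"] * n_tested)
    df["significant"] = df["p_adjusted"] < alpha
    return df
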