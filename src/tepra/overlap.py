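"""Interval overlap between subfamily elements and genomic annotations.

An element "overlaps" an annotation set when at least half of its length is
covered by (merged) annotation intervals.  Subfamily-level enrichment uses a
BEDTools-Fisher-style 2x2 whose fourth cell estimates the number of
annotation-sized slots in the rest of the genome; motif association asks
whether motif-bearing elements are the overlapping ones.  All coordinates
are 0-based half-open and strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tewas import fisher_two_sided


@dataclass
class AnnotationSet:
    name: str
    intervals: pd.DataFrame  # chrom, start, end
    merged: bool = False

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["end"] < df["start"]).any():
            raise ValueError("negative-length interval")
        if not self.merged:
            self.intervals = merge_intervals(df)
            self.merged = True

    @property
    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or bookended intervals per chromosome."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _coverage_bp(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp of [start,end) covered by sorted non-overlapping intervals."""
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if hi <= lo:
        return 0
    clip_s = np.maximum(starts[lo:hi], start)
    clip_e = np.minimum(ends[lo:hi], end)
    return int(np.maximum(clip_e - clip_s, 0).sum())


@dataclass
class OverlapResult:
    element_id: str
    overlapped: bool
    best_overlap_bp: int
    annotation: str


def overlap_elements(
    elements: pd.DataFrame,  # element_id, chrom, start, end
    annotation: AnnotationSet,
    min_frac: float = 0.5,
) -> list[OverlapResult]:
    """Flag elements with >= min_frac of their length under the annotation.

    Elements on chromosomes absent from the annotation simply do not
    overlap.
    """
    if (elements["end"] < elements["start"]).any():
        raise ValueError("negative-length element interval")
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in annotation.intervals.groupby("chrom", sort=True)
    }
    results = []
    for row in elements.itertuples(index=False):
        starts, ends = by_chrom.get(row.chrom, (np.array([]), np.array([])))
        bp = _coverage_bp(row.start, row.end, starts, ends)
        length = row.end - row.start
        results.append(
            OverlapResult(
                row.element_id, bp >= min_frac * length and length > 0, bp, annotation.name
            )
        )
    return results


@dataclass
class FisherEnrichment:
    table: tuple[int, int, int, int]
    odds_ratio: float
    odds_ratio_haldane: float
    p_value: float
    metadata: dict = field(default_factory=dict)


def fisher_enrichment(
    elements: pd.DataFrame,
    annotation: AnnotationSet,
    genome_size: int,
    min_frac: float = 0.5,
) -> FisherEnrichment:
    """Subfamily-vs-annotation enrichment, BEDTools-Fisher style.

    n11 = elements overlapping (>= min_frac), n12 = elements not
    overlapping, n21 = merged annotation intervals not hit by any element
    (>= 1 bp), n22 = max(0, genome_size / mean merged interval length -
    n11 - n12 - n21).  The contingency construction is recorded in the
    result metadata because BEDTools' own formula varies by version.
    """
    if len(elements) == 0 or len(annotation.intervals) == 0:
        raise ValueError("need at least one element and one annotation interval")
    if genome_size < annotation.total_bp:
        raise ValueError("genome_size smaller than annotated bp")
    overlaps = overlap_elements(elements, annotation, min_frac)
    n11 = sum(o.overlapped for o in overlaps)
    n12 = len(overlaps) - n11
    hit = np.zeros(len(annotation.intervals), dtype=bool)
    ann = annotation.intervals.reset_index(drop=True)
    for row in elements.itertuples(index=False):
        sel = (
            (ann["chrom"] == row.chrom)
            & (ann["start"] < row.end)
            & (ann["end"] > row.start)
        )
        hit |= sel.to_numpy()
    n21 = int((~hit).sum())
    mean_len = annotation.total_bp / len(ann)
    n22 = max(0, int(round(genome_size / mean_len)) - n11 - n12 - n21)
    p = fisher_two_sided(n11, n12, n21, n22)
    odds = (n11 * n22) / (n12 * n21) if n12 * n21 else float("inf")
    oh = ((n11 + 0.5) * (n22 + 0.5)) / ((n12 + 0.5) * (n21 + 0.5))
    return FisherEnrichment(
        (n11, n12, n21, n22),
        odds,
        oh,
        p,
        metadata={
            "construction": "n22 = genome_size/mean_merged_interval_len - n11 - n12 - n21",
            "genome_size": genome_size,
            "mean_interval_length": mean_len,
            "min_frac": min_frac,
            "annotation": annotation.name,
        },
    )


def motif_annotation_association(
    overlaps: list[OverlapResult],
    motif_hits: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-motif Fisher test of motif presence vs annotation overlap."""
    flagged = {o.element_id for o in overlaps if o.overlapped}
    unflagged = {o.element_id for o in overlaps if not o.overlapped}
    if not flagged or not unflagged:
        raise ValueError("need both overlapping and non-overlapping elements")
    motifs = sorted({m for hits in motif_hits.values() for m in hits})
    rows = []
    for m in motifs:
        a = sum(1 for e in flagged if m in motif_hits.get(e, set()))
        c = sum(1 for e in unflagged if m in motif_hits.get(e, set()))
        if a + c == 0:
            continue
        b, d = len(flagged) - a, len(unflagged) - c
        odds = (a * d) / (b * c) if b * c else float("inf")
        rows.append((m, a, b, c, d, odds, fisher_two_sided(a, b, c, d)))
    df = pd.DataFrame(
        rows,
        columns=["motif", "overlap_hit", "overlap_nohit", "other_hit", "other_nohit", "odds_ratio", "p_raw"],
    )
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * len(df))
    df["significant"] = df["p_bonferroni"] < alpha
    return df
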