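"""Barcode counts -> enrichment scores, activity calls, mutagenesis effects.

The scoring follows the standard MPRA recipe: sum barcode counts per
element, drop elements with fewer than five total counts in the DNA pool or
any RNA replicate, convert to counts per million over retained elements,
take RNA CPM / DNA CPM, normalize to the mean expression of the basal
promoter-only construct, and report the log2 as the enrichment score.  An
element is "active" when its score exceeds a strict threshold (default 1,
i.e. more than twofold over basal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def rna_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("rna_rep")]
    if not cols:
        raise ValueError("no rna_rep* columns in count table")
    return cols


def aggregate_and_filter(counts: pd.DataFrame, min_total: int = 5) -> pd.DataFrame:
    """Per-element summed counts with a retention flag.

    Retained iff the summed DNA count and every summed RNA replicate count
    are at least ``min_total``.  The sums are element-level (over all of an
    element's barcodes).
    """
    rna = rna_columns(counts)
    agg = counts.groupby("element_id", sort=True)[["dna", *rna]].sum()
    agg["n_barcodes"] = counts.groupby("element_id", sort=True).size()
    retained = agg["dna"] >= min_total
    for c in rna:
        retained &= agg[c] >= min_total
    agg["retained"] = retained
    if "fragment_kind" in counts.columns:
        agg["fragment_kind"] = counts.groupby("element_id", sort=True)[
            "fragment_kind"
        ].first()
    return agg.reset_index()


@dataclass
class EnrichmentTable:
    """Per-element, per-replicate basal-normalized log2 MPRA activity."""

    table: pd.DataFrame  # element_id, E_rep*, E, expression_rep*
    basal_element_ids: list[str]
    active: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("element_id")["E"]

    def classify_active(self, threshold: float, name: str | None = None) -> pd.Series:
        """Active iff E > threshold (strict); stored under ``name``."""
        labels = self.table.set_index("element_id")["E"] > threshold
        self.active[name or f"gt_{threshold:g}"] = labels
        return labels


def enrichment_scores(
    aggregated: pd.DataFrame, basal_element_ids: list[str]
) -> EnrichmentTable:
    """CPM-normalize, divide by basal mean expression, take log2.

    CPM columns are computed over retained elements only.  The basal mean is
    the arithmetic mean of basal expression values pooled over replicates.
    The per-element score E is the mean of the per-replicate log2 scores.
    """
    rna = rna_columns(aggregated)
    kept = aggregated[aggregated["retained"]].copy()
    basal_kept = [b for b in basal_element_ids if b in set(kept["element_id"])]
    if not basal_kept:
        raise ValueError("no retained basal element")
    cpm = {}
    cpm["dna"] = kept["dna"] / kept["dna"].sum() * 1e6
    for c in rna:
        cpm[c] = kept[c] / kept[c].sum() * 1e6
    expr = pd.DataFrame(
        {c: cpm[c].to_numpy() / cpm["dna"].to_numpy() for c in rna},
        index=kept["element_id"],
    )
    basal_mean = float(expr.loc[basal_kept].to_numpy().mean())
    out = pd.DataFrame({"element_id": kept["element_id"].to_numpy()})
    e_cols = []
    for i, c in enumerate(rna, start=1):
        out[f"expression_rep{i}"] = expr[c].to_numpy()
        out[f"E_rep{i}"] = np.log2(expr[c].to_numpy() / basal_mean)
        e_cols.append(f"E_rep{i}")
    out["E"] = out[e_cols].mean(axis=1)
    if "fragment_kind" in kept.columns:
        out["fragment_kind"] = kept["fragment_kind"].to_numpy()
    return EnrichmentTable(out, basal_kept)


def classify_active(
    table: EnrichmentTable, threshold: float = 1.0, name: str | None = None
) -> pd.Series:
    return table.classify_active(threshold, name)


@dataclass
class MutagenesisEffect:
    pairs: pd.DataFrame  # mutant_id, native_id, effect (log2 ratio)
    mean_effect: float
    mean_fold_change: float
    skipped: list[tuple[str, str]]

    def compare(self, other: "MutagenesisEffect") -> float:
        """Two-tailed Mann-Whitney U p-value between two effect groups."""
        a, b = self.pairs["effect"], other.pairs["effect"]
        if len(a) == 0 or len(b) == 0:
            return float("nan")
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def mutagenesis_effect(
    table: EnrichmentTable, pairs: list[tuple[str, str]]
) -> MutagenesisEffect:
    """Per-pair log2 ratio of mutant to native normalized expression.

    effect = E_mutant - E_native.  Pairs with either member missing (not
    retained) are skipped and recorded.  The group summary reports the mean
    effect and its fold-change 2^mean.
    """
    scores = table.scores
    rows = []
    skipped = []
    for mutant_id, native_id in pairs:
        if mutant_id in scores.index and native_id in scores.index:
            rows.append(
                (mutant_id, native_id, float(scores[mutant_id] - scores[native_id]))
            )
        else:
            skipped.append((mutant_id, native_id))
    df = pd.DataFrame(rows, columns=["mutant_id", "native_id", "effect"])
    mean_effect = float(df["effect"].mean()) if len(df) else float("nan")
    return MutagenesisEffect(df, mean_effect, 2.0**mean_effect, skipped)
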