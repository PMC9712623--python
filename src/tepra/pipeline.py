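"""End-to-end pipeline driver: synthetic or user-supplied data in, report out.

Stage order follows the dependency chain: generate/load sequences and
counts; project every element onto the reference; score the MPRA;
associate positions and motifs with activity; deconvolve tiled fragments;
test conservation and neutral motif retention; overlap with annotations.
Every output file carries a header naming the producing stage, its
parameters, and the seed, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, motifs as motif_lib
from .conservation import (
    expected_motif_conservation,
    observed_motif_conservation,
    proportion_test,
    shared_conserved_windows,
    simulate_motif_conservation,
    window_conservation,
)
from .mpra_scoring import aggregate_and_filter, enrichment_scores, mutagenesis_effect
from .overlap import AnnotationSet, fisher_enrichment, motif_annotation_association, overlap_elements
from .seqcore import (
    SequenceRecord,
    estimate_titv,
    global_align,
    project_to_reference,
    scan_motif,
)
from .sharpr import TilingDesign, deconvolve_elements
from .synthetic_data import (
    SimulationParams,
    build_library_design,
    simulate_mpra_counts,
    simulate_subfamily,
)
from .tewas import (
    associate_positions,
    association_frame,
    motif_ic_overrepresentation,
    motif_presence_enrichment,
)

log = logging.getLogger("tepra")

_KNOWN_KEYS = {
    "outdir",
    "seed",
    "synthetic",
    "fasta",
    "counts_tsv",
    "motifs_meme",
    "annotations_bed",
    "reference_id",
    "min_total",
    "active_threshold",
    "relaxed_threshold",
    "alpha",
    "tile_len",
    "tile_step",
    "varpriors",
    "peak_sd",
    "window_width",
    "window_max_excluded",
    "n_sims",
    "n_shuffles",
    "scan_p_threshold",
    "min_frac",
    "genome_size",
    "n_transposition_leaves",
    "stages",
}

_ALL_STAGES = ("simulate", "score", "tewas", "sharpr", "conserve", "overlap")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int
    synthetic: bool = True
    fasta: str | None = None
    counts_tsv: str | None = None
    motifs_meme: str | None = None
    annotations_bed: str | None = None
    reference_id: str = "root"
    min_total: int = 5
    active_threshold: float = 1.0
    relaxed_threshold: float = 0.5
    alpha: float = 5e-5
    tile_len: int = 160
    tile_step: int = 10
    varpriors: tuple[float, float] = (1.0, 50.0)
    peak_sd: float = 3.0
    window_width: int = 10
    window_max_excluded: int = 5
    n_sims: int = 1000
    n_shuffles: int = 1000
    scan_p_threshold: float = 1e-4
    min_frac: float = 0.5
    genome_size: int = 1_000_000
    n_transposition_leaves: int = 28
    stages: tuple[str, ...] = _ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw or "seed" not in raw:
            raise ValueError("config requires 'outdir' and 'seed'")
        cfg = cls(**raw)
        if not cfg.synthetic:
            for key in ("fasta", "counts_tsv"):
                p = getattr(cfg, key)
                if p is None:
                    raise ValueError(f"non-synthetic mode requires {key}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        return cfg

    def resolved_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["tool_version"] = __version__
        return yaml.safe_dump(d, sort_keys=True)


def _header(stage: str, cfg: PipelineConfig, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"stage={stage} seed={cfg.seed} version={__version__} {kv}".strip()


def select_clean_mutagenesis(
    records: list[SequenceRecord],
    truth,
    params: SimulationParams,
    max_pairs: int = 15,
) -> list[tuple[str, str, str]]:
    """Loss/gain mutagenesis targets whose edit is surgical.

    Loss candidates carry a forward motif hit at the planted span that does
    not overlap a hit of any other planted motif (so ablating it removes
    exactly one effect); gain candidates lack the motif entirely.
    """
    chosen: list[tuple[str, str, str]] = []
    present = [r for r in records if r.role == "present_day"]
    for pm in params.planted_motifs:
        others = [q.motif for q in params.planted_motifs if q is not pm]
        key = pm.motif.name
        n_loss = n_gain = 0
        for rec in present:
            if n_loss >= max_pairs and n_gain >= max_pairs:
                break
            if truth.motif_presence[rec.id][key]:
                if n_loss >= max_pairs:
                    continue
                hits = [
                    h
                    for h in scan_motif(rec.bases, pm.motif, params.scan_p_threshold)
                    if h.strand == "+"
                ]
                if not hits:
                    continue
                h = hits[0]
                span = range(h.offset, h.offset + pm.motif.k)
                clash = any(
                    max(span.start, o.offset) < min(span.stop, o.offset + om.k)
                    for om in others
                    for o in scan_motif(rec.bases, om, params.scan_p_threshold)
                )
                if not clash:
                    chosen.append((rec.id, pm.motif, "loss"))
                    n_loss += 1
            elif n_gain < max_pairs:
                chosen.append((rec.id, pm.motif, "gain"))
                n_gain += 1
    return chosen


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.resolved.yaml").write_text(config.resolved_yaml())
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "version": __version__}
    try:
        return _run(config, outdir, report)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, report: dict) -> dict:
    motif_models = (
        io.read_meme(config.motifs_meme)
        if config.motifs_meme
        else motif_lib.default_motifs()
    )

    # ---- stage: simulate (or load inputs)
    if config.synthetic:
        params = SimulationParams(
            seed=config.seed,
            n_transposition_leaves=config.n_transposition_leaves,
            scan_p_threshold=config.scan_p_threshold,
        )
        records, truth = simulate_subfamily(params)
        reference = next(r for r in records if r.role == "consensus")
        others = [r for r in records if r.id != reference.id]
        tiled_ids = [
            r.id for r in records if r.role in ("ortholog_ancestor", "tree_intermediate")
        ]
        mutagenesis = select_clean_mutagenesis(records, truth, params)
        design = build_library_design(
            others,
            reference,
            window=(0, config.tile_len),
            tile_len=config.tile_len,
            tile_step=config.tile_step,
            tiled_ids=tiled_ids,
            mutagenesis=mutagenesis,
            scan_p_threshold=config.scan_p_threshold,
        )
        counts = simulate_mpra_counts(truth, design, params)
        io.write_fasta(records, outdir / "sequences.fasta")
        (outdir / "tree.nwk").write_text(truth.tree_newick + "\n")
        (outdir / "truth.json").write_text(truth.to_json())
        io.write_tsv(counts, outdir / "counts.tsv", _header("simulate", config))
        log.info("simulate: %d records, %d fragments", len(records), len(design.fragments))
        report["n_records"] = len(records)
        report["n_fragments"] = len(design.fragments)
    else:
        records = io.read_fasta(config.fasta)
        counts = io.read_counts_tsv(config.counts_tsv)
        try:
            reference = next(
                r for r in records if r.id == config.reference_id or r.role == "consensus"
            )
        except StopIteration:
            raise ValueError(f"reference {config.reference_id!r} not in FASTA") from None
        others = [r for r in records if r.id != reference.id]
        design = None
        truth = None

    # ---- stage: seqcore projection + substitution rates
    alignments = (
        design.alignments
        if design is not None
        else {r.id: global_align(reference, r) for r in others}
    )
    matrix = project_to_reference(list(alignments.values()))
    (outdir / "alignment.a2m").write_text(matrix.to_gapped_fasta())
    present_by_species: dict[str, list[str]] = {}
    for r in others:
        if r.role == "present_day" and r.species:
            present_by_species.setdefault(r.species, []).append(r.id)
    titv = {
        sp: estimate_titv(matrix, ids, species=sp)
        for sp, ids in sorted(present_by_species.items())
    }
    io.write_tsv(
        pd.DataFrame(
            [
                (m.species, m.s_transition, m.s_transversion, m.aligned_bases)
                for m in titv.values()
            ],
            columns=["species", "s_transition", "s_transversion", "aligned_bases"],
        ),
        outdir / "titv.tsv",
        _header("seqcore", config),
    )
    report["titv"] = {
        sp: {"s_transition": m.s_transition, "s_transversion": m.s_transversion}
        for sp, m in titv.items()
    }

    # ---- stage: score
    enr = None
    if "score" in config.stages:
        agg = aggregate_and_filter(counts, config.min_total)
        basal_ids = sorted(
            agg.loc[agg.get("fragment_kind", "") == "basal", "element_id"]
        ) or ["basal"]
        enr = enrichment_scores(agg, basal_ids)
        enr.classify_active(config.active_threshold, "default")
        enr.classify_active(config.relaxed_threshold, "relaxed")
        out = enr.table.copy()
        out["active_default"] = enr.active["default"].to_numpy()
        out["active_relaxed"] = enr.active["relaxed"].to_numpy()
        io.write_tsv(
            out,
            outdir / "enrichment.tsv",
            _header("score", config, min_total=config.min_total, threshold=config.active_threshold),
        )
        report["n_scored"] = len(out)
        report["n_active_default"] = int(out["active_default"].sum())
        report["n_active_relaxed"] = int(out["active_relaxed"].sum())
        if design is not None and design.mutagenesis_pairs:
            groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
            for mut_id, nat_id in design.mutagenesis_pairs:
                frag = design.fragment(mut_id)
                groups.setdefault((frag.motif, frag.mode), []).append((mut_id, nat_id))
            mut_report = {}
            for (mkey, mode), pairs in sorted(groups.items()):
                eff = mutagenesis_effect(enr, pairs)
                mut_report[f"{mkey}_{mode}"] = {
                    "mean_effect_log2": eff.mean_effect,
                    "mean_fold_change": eff.mean_fold_change,
                    "n_pairs": len(eff.pairs),
                }
            report["mutagenesis"] = mut_report
        log.info("score: %d elements, %d active", report["n_scored"], report["n_active_default"])

    # ---- stage: tewas
    if "tewas" in config.stages and enr is not None:
        mf_scores = enr.table[enr.table.get("fragment_kind", "") == "motif_focused"]
        labels = pd.Series(
            (mf_scores["E"] > config.active_threshold).to_numpy(),
            index=[e.split("|")[0] for e in mf_scores["element_id"]],
        )
        assoc = associate_positions(matrix, labels, config.alpha)
        adf = association_frame(assoc)
        io.write_tsv(adf, outdir / "tewas_positions.tsv", _header("tewas", config, alpha=config.alpha))
        sig = set(adf.loc[adf["significant"], "position"])
        tested = set(adf["position"])
        spans = []
        for m in motif_models:
            fwd_hits = [h for h in scan_motif(reference.bases, m, config.scan_p_threshold) if h.strand == "+"]
            if fwd_hits:
                spans.append((m, (fwd_hits[0].offset, fwd_hits[0].offset + m.k)))
        ic = motif_ic_overrepresentation(
            sig, spans, tested, config.n_shuffles, seed=config.seed
        )
        io.write_tsv(
            pd.DataFrame(
                [
                    (r.motif, r.span[0], r.span[1], r.n_sig_in_motif, r.observed_ic_sum, r.p_value, r.reported)
                    for r in ic
                ],
                columns=["motif", "span_start", "span_end", "n_sig", "observed_ic_sum", "p_value", "reported"],
            ),
            outdir / "tewas_motif_ic.tsv",
            _header("tewas", config, shuffles=config.n_shuffles),
        )
        hits_per_element = {
            r.id: {
                m.name
                for m in motif_models
                if scan_motif(r.bases, m, config.scan_p_threshold)
            }
            for r in others
            if r.id in labels.index
        }
        active_ids = [e for e in labels.index if labels[e]]
        inactive_ids = [e for e in labels.index if not labels[e]]
        presence = motif_presence_enrichment(active_ids, inactive_ids, hits_per_element)
        io.write_tsv(presence, outdir / "motif_presence_enrichment.tsv", _header("tewas", config))
        report["tewas_n_significant"] = int(adf["significant"].sum())
        report["tewas_motifs_reported"] = [r.motif for r in ic if r.reported]
        log.info("tewas: %d significant positions", report["tewas_n_significant"])

    # ---- stage: sharpr
    if "sharpr" in config.stages and enr is not None:
        scores = enr.scores
        kinds = counts.drop_duplicates("element_id").set_index("element_id")
        lengths = {r.id: len(r.bases) for r in records}
        tile_designs: dict[str, list[tuple[int, float]]] = {}
        basal_designs: dict[str, list[tuple[int, float]]] = {}
        for frag_id in scores.index:
            if "|tile" not in frag_id:
                continue
            element_id, tile_part = frag_id.split("|tile")
            target = (
                basal_designs
                if kinds.loc[frag_id, "fragment_kind"] == "control_shuffle"
                else tile_designs
            )
            target.setdefault(element_id, []).append((int(tile_part), float(scores[frag_id])))
        def _mk(eid, tiles):
            length = lengths.get(eid, max(o for o, _ in tiles) + config.tile_len)
            return TilingDesign(eid, length, sorted(tiles), config.tile_len, config.tile_step)
        designs = [_mk(e, t) for e, t in sorted(tile_designs.items())]
        basals = [
            TilingDesign(e, max(o for o, _ in t) + config.tile_len, sorted(t), config.tile_len, config.tile_step)
            for e, t in sorted(basal_designs.items())
        ]
        if designs:
            tracks, basal_bg = deconvolve_elements(
                designs, basals, config.varpriors, config.peak_sd
            )
            io.write_tsv(
                pd.DataFrame(
                    [(t.element_id, t.sharpr_sum, len(t.peaks)) for t in tracks],
                    columns=["element_id", "sharpr_sum", "n_peaks"],
                ),
                outdir / "sharpr_sums.tsv",
                _header("sharpr", config, varpriors=config.varpriors, peak_sd=config.peak_sd),
            )
            peak_rows = [
                (t.element_id, s, e) for t in tracks for s, e in t.peaks
            ]
            io.write_bed(
                pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]),
                outdir / "sharpr_peaks.bed",
                _header("sharpr", config),
            )
            with open(outdir / "sharpr_tracks.bedgraph", "w") as fh:
                fh.write(f"# {_header('sharpr', config)}\n")
                for t in tracks:
                    for i, v in enumerate(t.nucleotide_values):
                        fh.write(f"{t.element_id}\t{i}\t{i + 1}\t{v:.5f}\n")
            report["sharpr_n_elements"] = len(tracks)
            report["sharpr_basal_sd"] = basal_bg.sd
            report["sharpr_mean_sum"] = float(np.mean([t.sharpr_sum for t in tracks]))
            log.info("sharpr: %d tracks", len(tracks))

    # ---- stage: conserve
    if "conserve" in config.stages and present_by_species:
        per_species = {}
        for sp, ids in sorted(present_by_species.items()):
            sub_matrix = project_to_reference(
                [alignments[i] for i in ids]
            )
            per_species[sp] = window_conservation(
                sub_matrix,
                sp,
                config.window_width,
                max_excluded=config.window_max_excluded,
            )
        all_windows = pd.concat(per_species.values())
        io.write_tsv(all_windows, outdir / "window_conservation.tsv", _header("conserve", config))
        shared = shared_conserved_windows(
            per_species, reference.bases, motif_models, config.scan_p_threshold
        )
        report["n_shared_conserved_windows"] = len(shared["window_starts"])
        cons_rows = []
        sim_dump = {}
        for m in motif_models:
            fwd = [h for h in scan_motif(reference.bases, m, config.scan_p_threshold) if h.strand == "+"]
            if not fwd:
                continue
            span = (fwd[0].offset, fwd[0].offset + m.k)
            anc_kmer = reference.bases[span[0] : span[1]]
            for sp, model in titv.items():
                expected = expected_motif_conservation(anc_kmer, m, model, config.scan_p_threshold)
                sp_matrix = project_to_reference([alignments[i] for i in present_by_species[sp]])
                observed, n = observed_motif_conservation(sp_matrix, span, m, config.scan_p_threshold)
                sims = simulate_motif_conservation(
                    [anc_kmer] * n, m, model, config.n_sims, seed=config.seed, p_threshold=config.scan_p_threshold
                )
                p = proportion_test(observed, expected, n)
                cons_rows.append((m.name, sp, "consensus_ancestral", expected, observed, n, p))
                sim_dump[f"{m.name}|{sp}"] = [float(x) for x in sims]
        cons_df = pd.DataFrame(
            cons_rows,
            columns=["motif", "species", "reference_kind", "expected_P", "observed_fraction", "n_elements", "prop_test_p"],
        )
        io.write_tsv(cons_df, outdir / "motif_conservation.tsv", _header("conserve", config, sims=config.n_sims))
        (outdir / "motif_conservation_sims.json").write_text(
            json.dumps(sim_dump, indent=0, sort_keys=True)
        )
        report["motif_conservation"] = cons_df.to_dict("records")
        log.info("conserve: %d shared windows", report["n_shared_conserved_windows"])

    # ---- stage: overlap
    if "overlap" in config.stages:
        rng = np.random.default_rng(config.seed + 7)
        present = [r for r in others if r.role == "present_day"]
        spacing = 2000
        el_rows = []
        for i, r in enumerate(present):
            start = 1000 + i * spacing
            el_rows.append((r.id, "chrSim", start, start + len(r.bases)))
        elements_df = pd.DataFrame(el_rows, columns=["element_id", "chrom", "start", "end"])
        if config.annotations_bed:
            ann_df = io.read_bed(config.annotations_bed)
        else:
            # synthetic cCRE-like peaks: cover motif-bearing elements at 80%,
            # others at 10%, plus background peaks
            peaks = []
            for (eid, chrom, s, e) in el_rows:
                dosage = sum(truth.motif_presence[eid].values()) if truth else 0
                p_cover = 0.8 if dosage >= 2 else (0.35 if dosage == 1 else 0.1)
                if rng.random() < p_cover:
                    peaks.append((chrom, s - 20, s + int(0.8 * (e - s))))
            for _ in range(40):
                pos = int(rng.integers(0, len(present) * spacing))
                peaks.append(("chrSim", pos, pos + 300))
            ann_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
        annotation = AnnotationSet("cCRE_synthetic" if not config.annotations_bed else "annotation", ann_df)
        overlaps = overlap_elements(elements_df, annotation, config.min_frac)
        genome_size = max(config.genome_size, annotation.total_bp, int(elements_df["end"].max()) + 1000)
        fisher = fisher_enrichment(elements_df, annotation, genome_size, config.min_frac)
        hits_all = {
            r.id: {m.name for m in motif_models if scan_motif(r.bases, m, config.scan_p_threshold)}
            for r in present
        }
        try:
            assoc = motif_annotation_association(overlaps, hits_all)
        except ValueError:
            assoc = pd.DataFrame()
        io.write_tsv(
            pd.DataFrame(
                [(o.element_id, o.overlapped, o.best_overlap_bp, o.annotation) for o in overlaps],
                columns=["element_id", "overlapped", "overlap_bp", "annotation"],
            ),
            outdir / "overlap_elements.tsv",
            _header("overlap", config, min_frac=config.min_frac),
        )
        if len(assoc):
            io.write_tsv(assoc, outdir / "overlap_motif_association.tsv", _header("overlap", config))
        report["overlap"] = {
            "n_overlapping": sum(o.overlapped for o in overlaps),
            "n_elements": len(overlaps),
            "fisher_table": fisher.table,
            "fisher_p": fisher.p_value,
            "odds_ratio": fisher.odds_ratio,
        }
        log.info("overlap: %d/%d elements", report["overlap"]["n_overlapping"], len(overlaps))

    # ---- summary
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    summary = ["# tepra pipeline summary", "", f"seed: {config.seed}", ""]
    for k in sorted(report):
        if k not in ("motif_conservation",):
            summary.append(f"- {k}: {report[k]}")
    (outdir / "summary.md").write_text("\n".join(summary) + "\n")
    return report
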