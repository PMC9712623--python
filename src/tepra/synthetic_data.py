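"""Synthetic TE subfamily with known history, planted motifs, and MPRA counts.

The generator emulates the two-phase history of an LTR subfamily: a
transposition phase in which copies multiply inside the ancestral genome
(modelled as a Yule birth tree with per-branch substitutions), followed by a
speciation phase in which each transposition-phase copy (an "ortholog
ancestor") evolves independently down per-species branches.  Motif
consensus k-mers are planted in the root; element activity is linear in
motif dosage; barcode counts are overdispersed negative binomials.  All
randomness flows through one seed, so outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import motifs as motif_lib
from .seqcore import (
    GAP,
    N,
    AlignScoring,
    MotifModel,
    PairwiseAlignment,
    SequenceRecord,
    decode,
    encode,
    extract_reference_window,
    global_align,
    scan_motif,
)

_TI_MAP = np.array([2, 3, 0, 1], dtype=np.int8)  # A->G, C->T, G->A, T->C
_TV_MAP1 = np.array([1, 0, 1, 0], dtype=np.int8)  # A->C, C->A, G->C, T->A
_TV_MAP2 = np.array([3, 2, 3, 2], dtype=np.int8)  # A->T, C->G, G->T, T->G


@dataclass
class PlantedMotif:
    motif: MotifModel
    position: int
    effect_size: float


@dataclass
class SpeciesBranch:
    name: str
    branch_length: float  # substitutions/site

    @property
    def s_transition(self) -> float:
        return 2.0 * self.branch_length / 3.0

    @property
    def s_transversion(self) -> float:
        return self.branch_length / 3.0


def default_species() -> list[SpeciesBranch]:
    return [
        SpeciesBranch("human", 0.010),
        SpeciesBranch("chimp", 0.012),
        SpeciesBranch("gorilla", 0.014),
        SpeciesBranch("gibbon", 0.020),
        SpeciesBranch("baboon", 0.025),
        SpeciesBranch("rhesus", 0.025),
        SpeciesBranch("marmoset", 0.040),
    ]


def default_planted_motifs() -> list[PlantedMotif]:
    return [
        PlantedMotif(motif_lib.jun_motif(), 30, 0.75),
        PlantedMotif(motif_lib.dbp_motif(), 70, 1.20),
    ]


@dataclass
class SimulationParams:
    seed: int
    root_length: int = 360
    planted_motifs: list[PlantedMotif] = field(default_factory=default_planted_motifs)
    n_transposition_leaves: int = 28
    species_list: list[SpeciesBranch] = field(default_factory=default_species)
    transposition_s_transition: float = 0.02
    transposition_s_transversion: float = 0.01
    indel_rate: float = 0.0005
    activity_baseline: float = 0.3
    activity_noise_sd: float = 0.25
    barcodes_per_element: int = 10
    basal_barcodes: int = 300
    rna_replicates: int = 3
    dna_mean_depth: float = 100.0
    nb_dispersion: float = 0.1
    n_shuffled_controls: int = 30
    scan_p_threshold: float = 1e-4

    def __post_init__(self) -> None:
        for r in (
            self.transposition_s_transition,
            self.transposition_s_transversion,
            self.indel_rate,
        ):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0,1]")
        for pm in self.planted_motifs:
            if not np.isfinite(pm.effect_size):
                raise ValueError("effect sizes must be finite")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticTruth:
    tree_newick: str
    sequences: dict[str, str]  # node name -> ungapped sequence
    motif_presence: dict[str, dict[str, bool]]  # element -> motif name -> bool
    true_activity: dict[str, float]  # element -> log2 units over basal
    params: SimulationParams

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree": self.tree_newick,
                "sequences": self.sequences,
                "motif_presence": self.motif_presence,
                "true_activity": self.true_activity,
            },
            indent=1,
            sort_keys=True,
        )


def _mutate(
    codes: np.ndarray,
    s_ti: float,
    s_tv: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of evolution: per-site K2P-style substitution, then indels."""
    L = len(codes)
    out = codes.copy()
    acgt = out < N
    u = rng.random(L)
    ti = acgt & (u < s_ti)
    tv = acgt & (u >= s_ti) & (u < s_ti + s_tv)
    out[ti] = _TI_MAP[out[ti]]
    which = rng.random(L) < 0.5
    tv1, tv2 = tv & which, tv & ~which
    out[tv1] = _TV_MAP1[out[tv1]]
    out[tv2] = _TV_MAP2[out[tv2]]
    if indel_rate > 0:
        n_events = rng.binomial(L, indel_rate)
        if n_events:
            positions = np.sort(rng.integers(0, L, size=n_events))[::-1]
            pieces = out
            for pos in positions:
                length = min(int(rng.geometric(0.5)), 9)
                if rng.random() < 0.5:  # deletion
                    pieces = np.delete(pieces, slice(pos, pos + length))
                else:  # insertion of random bases
                    ins = rng.integers(0, 4, size=length).astype(np.int8)
                    pieces = np.insert(pieces, pos, ins)
            out = pieces
    return out


def simulate_subfamily(
    params: SimulationParams,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Root -> Yule transposition tree -> per-leaf speciation.

    Returns every node of the history as a SequenceRecord (root as
    ``consensus``, internal transposition nodes as ``tree_intermediate``,
    transposition leaves as ``ortholog_ancestor``, species tips as
    ``present_day``) plus the ground truth needed for recovery tests.
    """
    if params.n_transposition_leaves < 1:
        raise ValueError("need at least one transposition leaf")
    rng = np.random.default_rng(params.seed)

    root = rng.integers(0, 4, size=params.root_length).astype(np.int8)
    for pm in params.planted_motifs:
        kmer = encode(pm.motif.consensus)
        root[pm.position : pm.position + len(kmer)] = kmer

    # --- transposition phase: Yule birth tree with named internal nodes
    counter = [0]

    def next_name(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    class _Node:
        __slots__ = ("name", "seq", "children", "depth")

        def __init__(self, name, seq, depth):
            self.name, self.seq, self.depth = name, seq, depth
            self.children: list[_Node] = []

    root_node = _Node("root", root, 0)
    leaves = [root_node]
    while len(leaves) < params.n_transposition_leaves:
        idx = int(rng.integers(0, len(leaves)))
        parent = leaves.pop(idx)
        for _ in range(2):
            child_seq = _mutate(
                parent.seq,
                params.transposition_s_transition,
                params.transposition_s_transversion,
                params.indel_rate,
                rng,
            )
            child = _Node(next_name("node"), child_seq, parent.depth + 1)
            parent.children.append(child)
            leaves.append(child)

    records: list[SequenceRecord] = []
    sequences: dict[str, str] = {}

    def register(name: str, seq: np.ndarray, species: str, role: str) -> None:
        bases = decode(seq)
        sequences[name] = bases
        records.append(SequenceRecord(name, species, bases, role))

    register("root", root, "ancestral", "consensus")

    def walk(node: "_Node") -> str:
        if not node.children:
            anc_name = f"anc_{node.name}" if node.name != "root" else "anc_root"
            register(anc_name, node.seq, "ancestral", "ortholog_ancestor")
            for sp in params.species_list:
                tip_seq = _mutate(
                    node.seq,
                    sp.s_transition,
                    sp.s_transversion,
                    params.indel_rate,
                    rng,
                )
                register(f"{anc_name}_{sp.name}", tip_seq, sp.name, "present_day")
            sp_clades = ",".join(
                f"{anc_name}_{sp.name}:{sp.branch_length}" for sp in params.species_list
            )
            return f"({sp_clades}){anc_name}:1"
        if node.name != "root":
            register(node.name, node.seq, "ancestral", "tree_intermediate")
        subtrees = ",".join(walk(ch) for ch in node.children)
        return f"({subtrees}){node.name}:1"

    newick = walk(root_node) + ";"

    # --- ground truth: motif presence via the scanner, activity linear in dosage
    motif_presence: dict[str, dict[str, bool]] = {}
    true_activity: dict[str, float] = {}
    for rec in records:
        presence = {
            pm.motif.name: bool(
                scan_motif(rec.bases, pm.motif, params.scan_p_threshold)
            )
            for pm in params.planted_motifs
        }
        motif_presence[rec.id] = presence
        noise = (
            float(rng.normal(0.0, params.activity_noise_sd))
            if params.activity_noise_sd > 0
            else 0.0
        )
        true_activity[rec.id] = params.activity_baseline + sum(
            pm.effect_size
            for pm in params.planted_motifs
            if presence[pm.motif.name]
        ) + noise

    truth = SyntheticTruth(newick, sequences, motif_presence, true_activity, params)
    return records, truth


# ---------------------------------------------------------------------------
# Library design


@dataclass
class Fragment:
    fragment_id: str
    element_id: str
    kind: str  # motif_focused | tile | mutagenesis | control_shuffle | basal
    sequence: str
    offset: int = 0
    flagged: bool = False
    motif: str = ""
    mode: str = ""
    true_activity: float | None = None


@dataclass
class LibraryDesign:
    fragments: list[Fragment]
    excluded: dict[str, str]
    mutagenesis_pairs: list[tuple[str, str]]  # (mutant fragment id, native fragment id)
    alignments: dict[str, PairwiseAlignment] = field(default_factory=dict)

    def fragment(self, fragment_id: str) -> Fragment:
        return next(f for f in self.fragments if f.fragment_id == fragment_id)


_REPLACEMENTS = {
    "JUN": (motif_lib.JUN_LOSS, motif_lib.JUN_GAIN),
    "DBP": (motif_lib.DBP_LOSS, motif_lib.DBP_GAIN),
}


def tile_offsets(length: int, tile_len: int = 160, step: int = 10) -> list[int]:
    """Tile start offsets: multiples of ``step``, final tile right-anchored."""
    if length <= tile_len:
        return [0]
    offsets = list(range(0, length - tile_len + 1, step))
    if offsets[-1] + tile_len < length:
        offsets.append(length - tile_len)
    return offsets


def build_library_design(
    sequences: Sequence[SequenceRecord],
    reference: SequenceRecord,
    window: tuple[int, int] = (0, 160),
    tile_len: int = 160,
    tile_step: int = 10,
    tiled_ids: Sequence[str] | None = None,
    mutagenesis: Sequence[tuple[str, MotifModel, str]] = (),
    min_len: int = 70,
    max_len: int = 160,
    forbidden_subsequences: Sequence[str] = (),
    scoring: AlignScoring | None = None,
    scan_p_threshold: float = 1e-4,
) -> LibraryDesign:
    """Motif-focused fragments, tiles, and mutagenesis fragments.

    ``mutagenesis`` entries are (element_id, motif, mode) with mode "loss"
    (overwrite the element's motif hit with the fixed scrambled string) or
    "gain" (write the consensus string over the motif-aligned region).
    Replacement strings are fixed per motif family, keyed on the leading
    token of the motif name.
    """
    if tile_len < tile_step:
        raise ValueError("tile_len must be >= tile_step")
    seq_by_id = {rec.id: rec for rec in sequences}
    alignments = {
        rec.id: global_align(reference, rec, scoring) for rec in sequences
    }
    extraction = extract_reference_window(
        list(alignments.values()), window, min_len, max_len, forbidden_subsequences
    )
    fragments: list[Fragment] = []
    frag_seq: dict[str, str] = {}
    for element_id, seq in extraction.fragments:
        fid = f"{element_id}|mf"
        fragments.append(Fragment(fid, element_id, "motif_focused", seq))
        frag_seq[element_id] = seq

    for element_id in tiled_ids or []:
        bases = seq_by_id[element_id].bases
        offs = tile_offsets(len(bases), tile_len, tile_step)
        flagged = len(bases) < tile_len
        for o in offs:
            fragments.append(
                Fragment(
                    f"{element_id}|tile{o}",
                    element_id,
                    "tile",
                    bases[o : o + tile_len],
                    offset=o,
                    flagged=flagged,
                )
            )

    pairs: list[tuple[str, str]] = []
    for element_id, motif, mode in mutagenesis:
        if element_id not in frag_seq:
            continue
        native = frag_seq[element_id]
        key = next((k for k in _REPLACEMENTS if k in motif.name.upper()), None)
        if key is None:
            raise ValueError(f"no replacement strings for motif {motif.name!r}")
        loss_str, gain_str = _REPLACEMENTS[key]
        if mode == "loss":
            hits = [
                h for h in scan_motif(native, motif, scan_p_threshold) if h.strand == "+"
            ] or scan_motif(native, motif, scan_p_threshold)
            if not hits:
                continue
            h = hits[0]
            mutated = native[: h.offset] + loss_str + native[h.offset + motif.k :]
        elif mode == "gain":
            span = _reference_span_in_query(
                alignments[element_id], window, motif, scan_p_threshold, reference
            )
            if span is None:
                continue
            qs, qe = span
            mutated = native[:qs] + gain_str + native[qe:]
        else:
            raise ValueError(f"unknown mutagenesis mode {mode!r}")
        fid = f"{element_id}|mut_{key}_{mode}"
        fragments.append(
            Fragment(fid, element_id, "mutagenesis", mutated, motif=key, mode=mode)
        )
        pairs.append((fid, f"{element_id}|mf"))

    return LibraryDesign(fragments, extraction.excluded, pairs, alignments)


def _reference_span_in_query(
    aln: PairwiseAlignment,
    window: tuple[int, int],
    motif: MotifModel,
    p_threshold: float,
    reference: SequenceRecord,
) -> tuple[int, int] | None:
    """Query-fragment coordinates of the reference's motif span inside window."""
    ref_window = reference.bases[window[0] : window[1]]
    hits = [h for h in scan_motif(ref_window, motif, p_threshold) if h.strand == "+"]
    if not hits:
        return None
    rstart = window[0] + hits[0].offset
    rend = rstart + motif.k
    rr = encode(aln.ref_row)
    qr = encode(aln.query_row)
    ref_cols = np.flatnonzero(rr != GAP)
    win_lo, win_hi = ref_cols[window[0]], ref_cols[window[1] - 1]
    q_in_window = (qr != GAP) & (np.arange(len(qr)) >= win_lo) & (
        np.arange(len(qr)) <= win_hi
    )
    qpos_before = np.cumsum(q_in_window)
    qs = int(qpos_before[ref_cols[rstart]] - (1 if q_in_window[ref_cols[rstart]] else 0))
    qe = int(qpos_before[ref_cols[rend - 1]])
    return qs, qe


# ---------------------------------------------------------------------------
# Count simulation


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2; Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-9:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def fragment_activity(
    frag: Fragment, truth: SyntheticTruth, rng: np.random.Generator
) -> float:
    """Ground-truth log2 activity of one designed fragment.

    Motif-focused fragments inherit the element's activity; tiles,
    mutagenesis and shuffled controls are scanned directly so that motif
    gains/losses in the fragment sequence take effect.  Basal is 0.
    """
    params = truth.params
    if frag.kind == "basal":
        return 0.0
    if frag.kind == "motif_focused" and frag.element_id in truth.true_activity:
        return truth.true_activity[frag.element_id]
    baseline = 0.0 if frag.kind == "control_shuffle" else params.activity_baseline
    total = baseline
    for pm in params.planted_motifs:
        if scan_motif(frag.sequence, pm.motif, params.scan_p_threshold):
            total += pm.effect_size
    if params.activity_noise_sd > 0:
        total += float(rng.normal(0.0, params.activity_noise_sd))
    return total


def simulate_mpra_counts(
    truth: SyntheticTruth,
    design: LibraryDesign,
    params: SimulationParams | None = None,
) -> pd.DataFrame:
    """Overdispersed barcode counts for a library design.

    DNA per barcode ~ NB(dna_mean_depth, nb_dispersion); RNA per barcode per
    replicate ~ NB(dna_count * 2^activity, nb_dispersion), so the expected
    RNA/DNA ratio of a basal barcode is 1.  Adds the basal construct
    (``basal_barcodes`` barcodes) and shuffled-root negative controls to the
    design in place.  Deterministic given params.seed.
    """
    params = params or truth.params
    if params.dna_mean_depth <= 0:
        raise ValueError("dna_mean_depth must be positive")
    if any(
        f.kind != "basal" and not f.sequence for f in design.fragments
    ):
        raise ValueError("designed fragment with empty sequence")
    rng = np.random.default_rng(params.seed + 1_000_003)

    if not any(f.kind == "basal" for f in design.fragments):
        design.fragments.append(Fragment("basal", "basal", "basal", ""))
    if not any(f.kind == "control_shuffle" for f in design.fragments):
        root = encode(truth.sequences["root"])
        for i in range(params.n_shuffled_controls):
            shuf = root[rng.permutation(len(root))]
            eid = f"shuffle{i}"
            for o in tile_offsets(len(shuf)):
                design.fragments.append(
                    Fragment(
                        f"{eid}|tile{o}",
                        eid,
                        "control_shuffle",
                        decode(shuf[o : o + 160]),
                        offset=o,
                    )
                )

    rows = []
    for frag in design.fragments:
        if frag.true_activity is None:
            frag.true_activity = fragment_activity(frag, truth, rng)
        n_bc = (
            params.basal_barcodes if frag.kind == "basal" else params.barcodes_per_element
        )
        dna = _nb_draw(
            rng, np.full(n_bc, params.dna_mean_depth), params.nb_dispersion
        )
        rna_mean = dna.astype(float) * 2.0 ** frag.true_activity
        rna = np.column_stack(
            [
                _nb_draw(rng, rna_mean, params.nb_dispersion)
                for _ in range(params.rna_replicates)
            ]
        )
        for b in range(n_bc):
            rows.append(
                (
                    f"{frag.fragment_id}_bc{b}",
                    frag.fragment_id,
                    frag.kind,
                    int(dna[b]),
                    *[int(x) for x in rna[b]],
                )
            )
    cols = ["barcode", "element_id", "fragment_kind", "dna"] + [
        f"rna_rep{r + 1}" for r in range(params.rna_replicates)
    ]
    return pd.DataFrame(rows, columns=cols)
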