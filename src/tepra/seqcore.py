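"""Sequence and motif primitives.

Everything downstream of raw FASTA lives on top of four primitives defined
here: optimal global pairwise alignment with affine gaps, projection of many
pairwise alignments onto the coordinate system of one reference copy,
log-odds PWM scanning with an exact score-distribution p-value threshold,
and transition/transversion rate estimation from the projected alignment.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# Base encoding shared across the package: A C G T N gap
ALPHABET = "ACGTN-"
A, C, G, T, N, GAP = range(6)
_CODE = {ch: i for i, ch in enumerate(ALPHABET)}
_COMPLEMENT = np.array([T, G, C, A, N, GAP], dtype=np.int8)

VALID_ROLES = frozenset(
    {"present_day", "ortholog_ancestor", "tree_intermediate", "consensus", "control"}
)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string over ACGTN- as int8 codes."""
    try:
        return np.array([_CODE[ch] for ch in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid sequence character: {exc.args[0]!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


@dataclass
class SequenceRecord:
    """One subfamily copy (or reconstructed/consensus/control sequence)."""

    id: str
    species: str
    bases: str
    role: str = "present_day"
    coords: tuple[str, int, int, str] | None = None  # chrom, start, end, strand

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.bases = self.bases.upper()
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid sequence character: {sorted(bad)[0]!r}")
        if self.role != "control" and not self.bases:
            raise ValueError(f"empty sequence for {self.id!r}")
        if self.coords is not None:
            chrom, start, end, strand = self.coords
            if end - start != len(self.bases):
                raise ValueError(
                    f"{self.id}: coords span {end - start} != length {len(self.bases)}"
                )
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignScoring:
    """Affine-gap scoring; a gap of length L costs open + (L-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class PairwiseAlignment:
    ref_id: str
    query_id: str
    ref_row: str
    query_row: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")

    @property
    def ref_seq(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def query_seq(self) -> str:
        return self.query_row.replace("-", "")


_NEG = -1e30  # effectively -inf but safe under addition


def global_align(
    ref: SequenceRecord | str,
    query: SequenceRecord | str,
    scoring: AlignScoring | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Gotoh).

    Ties during traceback are broken deterministically: diagonal
    (match/mismatch) over gap-in-query (query row shows '-') over
    gap-in-ref.  N scores as a mismatch against everything and is excluded
    from the identity fraction.
    """
    scoring = scoring or AlignScoring()
    ref_id, ref_seq = _as_pair(ref, "ref")
    query_id, query_seq = _as_pair(query, "query")
    if not ref_seq:
        raise ValueError("empty reference sequence")
    r = encode(ref_seq)
    q = encode(query_seq)
    n, m = len(r), len(q)
    go, ge = scoring.gap_open, scoring.gap_extend

    # substitution score per alignment cell; N never matches
    eq = (r[:, None] == q[None, :]) & (r[:, None] != N) & (q[None, :] != N)
    sub = np.where(eq, scoring.match, scoring.mismatch)

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in query row (consumes ref)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in ref row (consumes query)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = go + ge * np.arange(m)
    if n:
        Ix[1:, 0] = go + ge * np.arange(n)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + go, Ix[i - 1, 1:] + ge
        )
        # Iy[i,j] = max_{k<j} max(M[i,k], Ix[i,k]) + go + (j-1-k)*ge
        opener = np.maximum(M[i], Ix[i]) + go - ge * (np.arange(m + 1) + 1)
        Iy[i, 1:] = np.maximum.accumulate(opener[:-1]) + ge * (np.arange(1, m + 1))

    ref_row, query_row = _traceback(M, Ix, Iy, r, q, sub, go, ge)
    score = max(M[n, m], Ix[n, m], Iy[n, m])

    rr = encode(ref_row)
    qr = encode(query_row)
    comparable = (rr < N) & (qr < N)
    identity = float(np.mean(rr[comparable] == qr[comparable])) if comparable.any() else 0.0
    return PairwiseAlignment(ref_id, query_id, ref_row, query_row, float(score), identity)


def _as_pair(rec: SequenceRecord | str, default_id: str) -> tuple[str, str]:
    if isinstance(rec, SequenceRecord):
        return rec.id, rec.bases
    return default_id, str(rec).upper()


_TIE = 1e-9


def _traceback(M, Ix, Iy, r, q, sub, go, ge):
    i, j = len(r), len(q)
    scores = (M[i, j], Ix[i, j], Iy[i, j])
    best = max(scores)
    state = next(s for s in (0, 1, 2) if scores[s] >= best - _TIE)
    ref_row: list[str] = []
    query_row: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            ref_row.append(ALPHABET[r[i - 1]])
            query_row.append(ALPHABET[q[j - 1]])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            cand = (M[i, j], Ix[i, j], Iy[i, j])
        elif state == 1:  # gap in query
            ref_row.append(ALPHABET[r[i - 1]])
            query_row.append("-")
            target = Ix[i, j]
            i -= 1
            cand = (M[i, j] + go, Ix[i, j] + ge, Iy[i, j] + go)
        else:  # gap in ref
            ref_row.append("-")
            query_row.append(ALPHABET[q[j - 1]])
            target = Iy[i, j]
            j -= 1
            cand = (M[i, j] + go, Ix[i, j] + go, Iy[i, j] + ge)
        if i == 0 and j == 0:
            break
        state = next(s for s in (0, 1, 2) if cand[s] >= target - _TIE)
    return "".join(reversed(ref_row)), "".join(reversed(query_row))


@dataclass
class ReferenceAlignmentMatrix:
    """All subfamily copies projected onto one reference's coordinates.

    One column per reference position; query insertions relative to the
    reference are dropped.  ``retained_mask[c]`` is True iff at least 20% of
    elements have a base (non-gap) in column c — columns failing this are
    excluded from association and conservation scans.
    """

    ref_id: str
    ref_seq: str
    element_ids: list[str]
    data: np.ndarray  # (n_elements, ref_length) int8 codes
    retained_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    min_presence: float = 0.20

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.element_ids), len(self.ref_seq)):
            raise ValueError("matrix shape does not match element/reference lengths")
        if self.retained_mask is None:
            presence = np.mean(self.data != GAP, axis=0)
            self.retained_mask = presence >= self.min_presence

    @property
    def ref_length(self) -> int:
        return len(self.ref_seq)

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    def row(self, element_id: str) -> str:
        return decode(self.data[self.element_ids.index(element_id)])

    def to_gapped_fasta(self) -> str:
        """A2M-style dump: reference first, then one gapped row per element."""
        out = [f">{self.ref_id}", self.ref_seq]
        for eid, row in zip(self.element_ids, self.data):
            out.append(f">{eid}")
            out.append(decode(row))
        return "\n".join(out) + "\n"


def project_to_reference(
    alignments: Sequence[PairwiseAlignment], min_presence: float = 0.20
) -> ReferenceAlignmentMatrix:
    """Combine pairwise alignments sharing one reference into a matrix."""
    if not alignments:
        raise ValueError("no alignments to project")
    ref_id = alignments[0].ref_id
    ref_seq = alignments[0].ref_seq
    rows = []
    ids = []
    for aln in alignments:
        if aln.ref_id != ref_id or aln.ref_seq != ref_seq:
            raise ValueError(
                f"alignment for {aln.query_id!r} has a different reference"
            )
        rr = encode(aln.ref_row)
        qr = encode(aln.query_row)
        rows.append(qr[rr != GAP])  # drop query-insertion columns
        ids.append(aln.query_id)
    return ReferenceAlignmentMatrix(
        ref_id, ref_seq, ids, np.vstack(rows), min_presence=min_presence
    )


@dataclass
class WindowExtraction:
    fragments: list[tuple[str, str]]
    excluded: dict[str, str]  # element_id -> reason


def extract_reference_window(
    alignments: Sequence[PairwiseAlignment],
    window: tuple[int, int],
    min_len: int = 70,
    max_len: int = 160,
    forbidden_subsequences: Iterable[str] = (),
) -> WindowExtraction:
    """Per-element sequence aligned to a reference window, insertions kept.

    The window is [start, end) on the ungapped reference.  Alignment columns
    from the first reference base of the window through its last reference
    base are taken, so insertions strictly inside the window are included
    while flanking insertions are not.  Elements shorter than ``min_len``
    (deletions), longer than ``max_len`` (insertions), or containing a
    forbidden subsequence (e.g. a cloning restriction site) are excluded
    with the reason recorded.
    """
    start, end = window
    if not alignments:
        raise ValueError("no alignments")
    ref_len = len(alignments[0].ref_seq)
    if not (0 <= start < end <= ref_len):
        raise ValueError(f"window [{start},{end}) out of range for reference of length {ref_len}")
    forbidden = [f.upper() for f in forbidden_subsequences]
    fragments: list[tuple[str, str]] = []
    excluded: dict[str, str] = {}
    for aln in alignments:
        rr = encode(aln.ref_row)
        ref_cols = np.flatnonzero(rr != GAP)
        lo, hi = ref_cols[start], ref_cols[end - 1]
        seq = aln.query_row[lo : hi + 1].replace("-", "")
        if len(seq) < min_len:
            excluded[aln.query_id] = "too_short"
        elif len(seq) > max_len:
            excluded[aln.query_id] = "too_long"
        elif any(f in seq for f in forbidden):
            excluded[aln.query_id] = "forbidden_subsequence"
        else:
            fragments.append((aln.query_id, seq))
    return WindowExtraction(fragments, excluded)


# ---------------------------------------------------------------------------
# PWM model and scanning


@dataclass
class MotifModel:
    """Position weight matrix with log-odds scores against a background.

    Log-odds use a 1e-3 pseudocount (rows renormalized) to avoid -inf on
    zero cells.  Scores are handled on an integer grid (``_SCALE`` units per
    bit) so that the exact score-distribution p-value threshold and window
    scoring share one representation.
    """

    name: str
    prob_matrix: np.ndarray  # (k, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    _SCALE = 10_000

    def __post_init__(self) -> None:
        self.prob_matrix = np.asarray(self.prob_matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.prob_matrix.ndim != 2 or self.prob_matrix.shape[1] != 4:
            raise ValueError("prob_matrix must be k x 4")
        if self.k < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.prob_matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("prob_matrix rows must sum to 1")
        q = (self.prob_matrix + self.pseudocount) / (1 + 4 * self.pseudocount)
        self.log_odds = np.log2(q / self.background)
        self._int_scores = np.rint(self.log_odds * self._SCALE).astype(np.int64)
        self._threshold_cache: dict[float, tuple[float, int]] = {}

    @property
    def k(self) -> int:
        return int(self.prob_matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.prob_matrix, axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits under a uniform background: 2 + sum p log2 p."""
        p = self.prob_matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def score(self, kmer: str) -> float:
        codes = encode(kmer)
        if len(codes) != self.k or np.any(codes >= N):
            raise ValueError("k-mer must be N-free and motif-width")
        return float(self.log_odds[np.arange(self.k), codes].sum())

    def threshold_for_p(self, p_threshold: float) -> tuple[float, int]:
        """Smallest score t with P(S >= t) <= p under the background.

        The score distribution is computed exactly by dynamic programming on
        the integer score grid.  Returns (score in bits, integer score).
        """
        if not (0 < p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if p_threshold in self._threshold_cache:
            return self._threshold_cache[p_threshold]
        ints = self._int_scores
        lo = int(ints.min(axis=1).sum())
        hi = int(ints.max(axis=1).sum())
        pmf = np.zeros(hi - lo + 1)
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(self.k):
            col = ints[i]
            new_lo = cur_lo + int(col.min())
            new = np.zeros(len(cur) + int(col.max() - col.min()))
            for b in range(4):
                shift = int(col[b]) - int(col.min())
                new[shift : shift + len(cur)] += cur * self.background[b]
            cur = new
            cur_lo = new_lo
        pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
        sf = np.cumsum(pmf[::-1])[::-1]  # P(S >= lo + idx)
        above = np.flatnonzero(sf <= p_threshold + 1e-12)
        t_int = lo + int(above[0]) if len(above) else hi + 1
        if p_threshold >= 1.0:
            t_int = lo
        result = (t_int / self._SCALE, t_int)
        self._threshold_cache[p_threshold] = result
        return result


@dataclass
class MotifHit:
    offset: int
    strand: str
    score: float


def scan_motif(
    seq: str,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All windows scoring at or above the exact p-value threshold.

    Offsets are on the forward strand; a minus-strand hit at offset o covers
    seq[o:o+k].  Windows containing N are disqualified.  Sequences shorter
    than the motif return no hits.
    """
    _, t_int = motif.threshold_for_p(p_threshold)
    hits: list[MotifHit] = []
    codes = encode(seq)
    if np.any(codes == GAP):
        raise ValueError("gap character in scanned sequence")
    k = motif.k
    L = len(codes)
    if L < k:
        return []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        sc = codes if strand == "+" else _COMPLEMENT[codes][::-1]
        ints = np.zeros(L - k + 1, dtype=np.int64)
        valid = np.ones(L - k + 1, dtype=bool)
        for i in range(k):
            window = sc[i : L - k + 1 + i]
            valid &= window < N
            ints += motif._int_scores[i, np.where(window < N, window, 0)]
        for o in np.flatnonzero(valid & (ints >= t_int)):
            offset = int(o) if strand == "+" else L - k - int(o)
            hits.append(MotifHit(offset, strand, float(ints[o]) / motif._SCALE))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Substitution-rate estimation


@dataclass
class SubstitutionModel:
    """Per-site single-step substitution probabilities for one species.

    Kimura-style: one transition probability, one total transversion
    probability split evenly over the two possible transversion targets.
    """

    species: str
    s_transition: float
    s_transversion: float
    aligned_bases: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.s_transition <= 1 and 0 <= self.s_transversion <= 1):
            raise ValueError("rates must be in [0,1]")
        if self.s_transition + self.s_transversion > 1 + 1e-12:
            raise ValueError("s_transition + s_transversion must be <= 1")

    @property
    def s_stay(self) -> float:
        return 1.0 - self.s_transition - self.s_transversion

    def step_matrix(self) -> np.ndarray:
        """4x4 per-site substitution probability matrix (A,C,G,T order)."""
        st, sv = self.s_transition, self.s_transversion
        P = np.full((4, 4), sv / 2.0)
        np.fill_diagonal(P, self.s_stay)
        transitions = [(A, G), (G, A), (C, T), (T, C)]
        for a, b in transitions:
            P[a, b] = st
        return P


_PURINE = {A, G}


def is_transition(a: int, b: int) -> bool:
    return a != b and ((a in _PURINE) == (b in _PURINE))


def estimate_titv(
    matrix: ReferenceAlignmentMatrix,
    element_subset: Sequence[str] | None = None,
    species: str = "",
) -> SubstitutionModel:
    """Pooled transition/transversion rates of elements vs the reference.

    Only positions where both the reference and the element carry A/C/G/T
    are counted; counts are summed over the subset before dividing.
    """
    if element_subset is None:
        idx = np.arange(matrix.n_elements)
    else:
        idx = np.array([matrix.element_ids.index(e) for e in element_subset])
    if len(idx) == 0:
        raise ValueError("empty element subset")
    ref = encode(matrix.ref_seq)
    sub = matrix.data[idx]
    valid = (sub < N) & (ref[None, :] < N)
    ref_b = np.broadcast_to(ref, sub.shape)
    diff = valid & (sub != ref_b)
    purine_ref = (ref_b == A) | (ref_b == G)
    purine_el = (sub == A) | (sub == G)
    ti = int(np.sum(diff & (purine_ref == purine_el)))
    tv = int(np.sum(diff & (purine_ref != purine_el)))
    aligned = int(valid.sum())
    if aligned == 0:
        raise ValueError("zero aligned bases")
    return SubstitutionModel(species, ti / aligned, tv / aligned, aligned)
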