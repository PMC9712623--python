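"""Format glue: FASTA, MEME minimal motifs, BED, and TSV tables.

FASTA descriptions carry ``key=value`` metadata tokens (species, role,
coords) so that a round trip through disk preserves SequenceRecord fields.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .seqcore import MotifModel, SequenceRecord


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        coords = None
        if "coords" in meta:
            chrom, span, strand = meta["coords"].split(":")
            start, end = span.split("-")
            coords = (chrom, int(start), int(end), strand)
        records.append(
            SequenceRecord(
                id=rec.id,
                species=meta.get("species", ""),
                bases=str(rec.seq),
                role=meta.get("role", "present_day"),
                coords=coords,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        desc = f"species={r.species} role={r.role}"
        if r.coords:
            chrom, start, end, strand = r.coords
            desc += f" coords={chrom}:{start}-{end}:{strand}"
        bio.append(BioSeqRecord(Seq(r.bases), id=r.id, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path: str | Path) -> list[MotifModel]:
    """Parse MEME minimal format (MOTIF blocks with letter-probability matrices)."""
    text = Path(path).read_text()
    background = np.full(4, 0.25)
    motifs: list[MotifModel] = []
    lines = iter(text.splitlines())
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("Background letter frequencies"):
            freq_line = next(lines).split()
            background = np.array(
                [float(freq_line[freq_line.index(b) + 1]) for b in "ACGT"]
            )
        elif stripped.startswith("MOTIF"):
            name = stripped.split()[1]
            rows = []
            w = None
            for sub in lines:
                s = sub.strip()
                if s.startswith("letter-probability matrix"):
                    match = re.search(r"w=\s*(\d+)", s)
                    w = int(match.group(1)) if match else None
                    continue
                if s and (s[0].isdigit() or s[0] == "0" or s[0] == "."):
                    rows.append([float(x) for x in s.split()])
                    if w is not None and len(rows) == w:
                        break
                elif rows:
                    break
            motifs.append(MotifModel(name, np.array(rows), background=background))
    return motifs


def write_meme(motifs: Iterable[MotifModel], path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    motifs = list(motifs)
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    buf.write(
        "Background letter frequencies\n"
        + " ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg))
        + "\n\n"
    )
    for m in motifs:
        buf.write(f"MOTIF {m.name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {m.k} nsites= 20 E= 0\n")
        for row in m.prob_matrix:
            buf.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# BED (0-based half-open)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    if (df["end"] < df["start"]).any():
        raise ValueError("negative-length interval in BED")
    return df


def write_bed(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Barcode count table: barcode, element_id, [fragment_kind,] dna, rna_rep*."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"barcode", "element_id", "dna"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df
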