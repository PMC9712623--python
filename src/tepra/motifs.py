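"""Built-in transcription-factor motif models.

These are synthetic stand-ins for the AP-1 (JUN) and CEBP-family (DBP)
position weight matrices: simple confidence profiles around the canonical
consensus 11-mers (TGAnTCA core for AP-1, TTATGTAA D-box core for DBP).
They are NOT the HOCOMOCO matrices; real PWMs can be supplied in MEME
minimal format and used everywhere these are.
"""

from __future__ import annotations

import numpy as np

from .seqcore import MotifModel

# Mutagenesis replacement strings: scrambled low-information sequences used
# to ablate a motif ("loss") and the consensus written in to create one
# ("gain").
JUN_LOSS = "TCACCAATGGT"
DBP_LOSS = "TCCCACAGCAT"
JUN_GAIN = "GCTGAGTCATG"
DBP_GAIN = "ATTATGTAACC"

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def pwm_from_consensus(
    name: str, consensus: str, confidence: "np.ndarray | list[float] | float"
) -> MotifModel:
    """PWM whose row i puts ``confidence[i]`` on the consensus base.

    The remaining mass is split evenly over the three other bases; a scalar
    confidence applies to every position.
    """
    k = len(consensus)
    conf = np.broadcast_to(np.asarray(confidence, dtype=float), (k,))
    mat = np.empty((k, 4))
    for i, base in enumerate(consensus.upper()):
        c = conf[i]
        mat[i] = (1.0 - c) / 3.0
        mat[i, _BASE_INDEX[base]] = c
    return MotifModel(name, mat)


def jun_motif() -> MotifModel:
    """AP-1-like 11-mer (synthetic): strong TGAGTCA core, softer flanks."""
    conf = [0.65, 0.65, 0.95, 0.95, 0.95, 0.92, 0.95, 0.95, 0.92, 0.65, 0.65]
    return pwm_from_consensus("JUN_synthetic", JUN_GAIN, conf)


def dbp_motif() -> MotifModel:
    """CEBP/DBP-like 11-mer (synthetic): strong TTATGTAA D-box, softer flanks."""
    conf = [0.65, 0.92, 0.95, 0.95, 0.92, 0.95, 0.95, 0.92, 0.92, 0.65, 0.65]
    return pwm_from_consensus("DBP_synthetic", DBP_GAIN, conf)


def default_motifs() -> list[MotifModel]:
    return [jun_motif(), dbp_motif()]
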