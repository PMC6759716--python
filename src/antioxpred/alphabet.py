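"""Amino-acid alphabet, secondary-structure states, and background frequencies.

All feature blocks in this package are laid out in the fixed PSI-BLAST
column order ``ARNDCQEGHILKMFPSTWYV`` (alanine first, valine last); every
matrix column index and every n-gram slot is derived from this string.
"""

from __future__ import annotations

import numpy as np

#: PSI-BLAST PSSM column order; also the 1-gram feature order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Secondary-structure states: helix, strand, coil.
SS_STATES = "HEC"

#: ss2 probability column order (coil, helix, strand).
SS_PROB_ORDER = "CHE"

#: Robinson-Robinson amino-acid background frequencies in AA_ORDER.
#: These are the standard PSI-BLAST residue background composition.
ROBINSON_ROBINSON = np.array(
    [
        0.07805,  # A
        0.05129,  # R
        0.04487,  # N
        0.05364,  # D
        0.01925,  # C
        0.04264,  # Q
        0.06295,  # E
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.09019,  # L
        0.05744,  # K
        0.02243,  # M
        0.03856,  # F
        0.05203,  # P
        0.07120,  # S
        0.05841,  # T
        0.01330,  # W
        0.03217,  # Y
        0.06441,  # V
    ]
)


def validate_background(bf: np.ndarray) -> np.ndarray:
    """Validate a 20-vector of background frequencies.

    Entries must lie in (0, 1) and sum to 1 within 5%.
    """
    bf = np.asarray(bf, dtype=float)
    if bf.shape != (20,):
        raise ValueError(f"background frequencies must have 20 entries, got {bf.shape}")
    if not np.all((bf > 0) & (bf < 1)):
        raise ValueError("background frequencies must lie strictly in (0, 1)")
    total = bf.sum()
    if not (0.95 <= total <= 1.05):
        raise ValueError(f"background frequencies sum to {total:.4f}, outside [0.95, 1.05]")
    return bf
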