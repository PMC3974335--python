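"""Shared scoring constants: amino-acid alphabet, substitution matrix, backgrounds.

The 20-letter alphabet is extended with ``X`` (index 20) for ambiguous or
masked residues. All scoring code treats X as the background-average
residue: its PSSM score is 0 bits and it never counts as an identity.
"""
from __future__ import annotations

import functools

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_X = AA + "X"
X_INDEX = 20
AA_TO_INDEX = {c: i for i, c in enumerate(AA_X)}

#: BLAST-family default affine gap penalties (cost of a length-k gap is
#: GAP_OPEN + k * GAP_EXTEND).
GAP_OPEN = 11.0
GAP_EXTEND = 1.0

# Robinson & Robinson amino-acid background frequencies.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

BACKGROUND = np.array([_ROBINSON[c] for c in AA], dtype=float)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Polar residues used for the composition-bias fraction.
POLAR_RESIDUES = frozenset("DEKRHNQSTYC")


@functools.lru_cache(maxsize=1)
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 float matrix in this package's alphabet order."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21), dtype=float)
    for i, a in enumerate(AA_X):
        for j, b in enumerate(AA_X):
            out[i, j] = m[a, b]
    return out


@functools.lru_cache(maxsize=1)
def blosum62_exchange_probs() -> np.ndarray:
    """Conditional substitution probabilities P(b | a) implied by BLOSUM62.

    BLOSUM62 entries are half-bit log-odds, so target frequencies are
    proportional to ``g_b * 2**(S_ab / 2)``. The diagonal is zeroed: a
    substitution event always changes the residue.
    """
    s = blosum62()[:20, :20]
    p = BACKGROUND[None, :] * np.power(2.0, s / 2.0)
    np.fill_diagonal(p, 0.0)
    return p / p.sum(axis=1, keepdims=True)


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int64 indices (X -> 20)."""
    return np.array([AA_TO_INDEX[c] for c in residues], dtype=np.int64)


def kd_values(residues: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE[c] for c in residues], dtype=float)
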