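"""Three-axis embedding of the family's identity structure.

Classical (Torgerson) multidimensional scaling of the distance
``d_ij = 1 - pid_ij / 100`` over the 50% non-redundant set: the squared
distances are double-centered, the top three eigenpairs give the
coordinates, and negative eigenvalues (non-Euclidean residue of the
identity measure) are truncated to zero. The best representative is
flagged so its position relative to the family's dispersion is visible.

Sign convention: the first nonzero coordinate along each axis is made
positive, so the embedding is reproducible across orderings up to that
convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pairwise import IdentityMatrix


@dataclass
class EmbeddingCoords:
    ids: list[str]
    coords: np.ndarray  # (n, 3)
    explained: np.ndarray  # (3,) fractions of the positive spectrum
    brs_id: str

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.ids), 3):
            raise ValueError("coords must be (n, 3)")
        if np.any(np.diff(self.explained) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "is_brs": [int(i == self.brs_id) for i in self.ids],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return Path(path)


def mds_embed(matrix: IdentityMatrix, brs_id: str) -> EmbeddingCoords:
    """Classical MDS of ``1 - identity/100`` down to three axes."""
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("embedding needs at least 3 sequences")
    if brs_id not in matrix.ids:
        raise ValueError(f"brs id {brs_id!r} not in matrix")
    d = 1.0 - matrix.pid / 100.0
    d2 = d * d
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    top = np.clip(eigvals[:3], 0.0, None)
    coords = eigvecs[:, :3] * np.sqrt(top)[None, :]
    for axis in range(3):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    positive_total = np.clip(eigvals, 0.0, None).sum()
    if positive_total > 0:
        explained = top / positive_total
    else:
        explained = np.zeros(3)
    return EmbeddingCoords(list(matrix.ids), coords, explained, brs_id)


def embedding_stress(coords: np.ndarray, matrix: IdentityMatrix) -> float:
    """Root-mean-square error between embedded and input distances."""
    d_in = 1.0 - matrix.pid / 100.0
    diff = coords[:, None, :] - coords[None, :, :]
    d_out = np.sqrt((diff * diff).sum(axis=2))
    n = d_in.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.sqrt(np.mean((d_in[iu] - d_out[iu]) ** 2)))
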