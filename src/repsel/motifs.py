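"""Ordered-motif family assignment: the second recognition engine.

Conserved ungapped blocks are extracted from the profile alignment and a
query belongs to the family if it carries enough of those blocks, in the
family's order, at roughly the family's spacing. This engine is
deliberately independent of full-length profile scoring: it can accept a
short sequence carrying the signature motifs and reject a long sequence
that matches diffusely.

Column conservation is the normalized-entropy complement
``1 - H(f') / log2(20)`` computed from lightly regularized column
frequencies (a dedicated small pseudocount, not the heavier scoring
blend, so an invariant column scores near 1).

The per-query decision combines motif count, order and spacing as
explicit rules; conservation enters through which motifs exist at all.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._scoring import AA, encode
from .profile import Pssm, Profile, henikoff_weights
from .seqio import ProteinSequence

DEFAULT_W_MIN = 5
DEFAULT_W_MAX = 40
DEFAULT_MIN_CONSERVATION = 0.6
DEFAULT_MAX_MOTIFS = 10
#: exactly two-thirds: with 3 motifs, 2 found suffice (ceil(2/3 * 3) == 2)
DEFAULT_MIN_FRACTION = 2.0 / 3.0
DEFAULT_BITS_PER_COLUMN = 0.5
DEFAULT_SPACING_TOLERANCE = 0.5
#: Pseudocount weight used for conservation only (light regularization).
CONSERVATION_PSEUDOCOUNT = 0.1

_LOG2_20 = math.log2(20.0)


@dataclass
class Motif:
    """One conserved ungapped block in seed coordinates (1-based)."""

    index: int
    start: int
    width: int
    column_scores: np.ndarray
    sub_pssm: np.ndarray  # (width, 21), X column zero

    def __post_init__(self) -> None:
        if self.width != len(self.column_scores) or self.width != self.sub_pssm.shape[0]:
            raise ValueError("motif width inconsistent with scores")

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    @property
    def mean_conservation(self) -> float:
        return float(np.mean(self.column_scores))

    def consensus(self) -> str:
        return "".join(AA[j] for j in np.argmax(self.sub_pssm[:, :20], axis=1))


@dataclass
class MotifSet:
    family_id: str
    motifs: list[Motif]
    spacing: list[int]

    def __post_init__(self) -> None:
        prev_end = 0
        for m in self.motifs:
            if m.start <= prev_end:
                raise ValueError("motifs must be non-overlapping and increasing")
            prev_end = m.end
        if self.motifs and len(self.spacing) != len(self.motifs) - 1:
            raise ValueError("spacing length must be n_motifs - 1")

    def __len__(self) -> int:
        return len(self.motifs)

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {
                "index": m.index,
                "start": m.start,
                "end": m.end,
                "width": m.width,
                "mean_conservation": round(m.mean_conservation, 4),
                "consensus": m.consensus(),
            }
            for m in self.motifs
        ]
        pd.DataFrame(
            rows,
            columns=["index", "start", "end", "width", "mean_conservation", "consensus"],
        ).to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class MotifHit:
    motif_index: int
    query_start: int  # 1-based
    score: float


@dataclass
class MotifAssignment:
    assigned: bool
    found: list[MotifHit]
    total_score: float


def conservation_from_probs(probs: np.ndarray) -> float:
    """Normalized-entropy complement of a frequency vector."""
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return max(0.0, min(1.0, 1.0 - h / _LOG2_20))


def _conservation_probs(profile: Profile | Pssm) -> np.ndarray:
    """Column frequencies under the light conservation pseudocount."""
    if isinstance(profile, Pssm):
        pssm = profile
        rows = None
    else:
        pssm = profile.pssm
        rows = profile.hit_alignment.rows
    g = pssm.background
    b = CONSERVATION_PSEUDOCOUNT
    if rows is None:
        # fall back to inverting the scoring blend from stored f'
        n_eff = 1.0
        freqs = pssm.probs * (n_eff + pssm.pseudocount_weight) - pssm.pseudocount_weight * g
        freqs = np.clip(freqs / n_eff, 0.0, None)
        tot = freqs.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        freqs = freqs / tot
        return (freqs + b * g[None, :]) / (1.0 + b)
    weights = henikoff_weights(rows)
    L = pssm.length
    freqs = np.zeros((L, 20))
    distinct = np.zeros(L)
    for col in range(L):
        seen = set()
        for w, row in zip(weights, rows):
            ch = row[col]
            if ch in "-X":
                continue
            freqs[col, AA.index(ch)] += w
            seen.add(ch)
        distinct[col] = len(seen)
    tot = freqs.sum(axis=1, keepdims=True)
    occupied = tot[:, 0] > 0
    freqs[occupied] /= tot[occupied]
    freqs[~occupied] = g
    n_eff = np.where(occupied, distinct, 1.0)[:, None]
    return (n_eff * freqs + b * g[None, :]) / (n_eff + b)


def column_conservation(profile: Profile | Pssm, column: int) -> float:
    """Conservation of one 1-based profile column, in [0, 1]."""
    probs = _conservation_probs(profile)
    if not 1 <= column <= probs.shape[0]:
        raise ValueError("column out of range")
    return conservation_from_probs(probs[column - 1])


def extract_motifs(
    profile: Profile | Pssm,
    w_min: int = DEFAULT_W_MIN,
    min_conservation: float = DEFAULT_MIN_CONSERVATION,
    max_motifs: int = DEFAULT_MAX_MOTIFS,
    w_max: int = DEFAULT_W_MAX,
    family_id: str = "",
) -> MotifSet:
    """Maximal conserved runs of length >= ``w_min`` become motifs.

    Runs longer than ``w_max`` are split into nearly equal adjacent
    blocks: ungapped matching of a very wide block is destroyed by a
    single indel, while a chain of moderate blocks with order and
    spacing constraints keeps specificity and tolerates indels. If more
    than ``max_motifs`` qualify, the best by mean conservation are kept
    and re-sorted by start. No qualifying run yields an empty MotifSet
    (the motif engine then reports coverage 0).
    """
    pssm = profile if isinstance(profile, Pssm) else profile.pssm
    if pssm.length < w_min:
        raise ValueError("profile shorter than w_min")
    probs = _conservation_probs(profile)
    cons = np.array([conservation_from_probs(p) for p in probs])
    scores_x = pssm.scores_with_x()

    runs: list[tuple[int, int]] = []  # 0-based [start, end)
    start = None
    for i, c in enumerate(cons):
        if c >= min_conservation:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(cons)))
    runs = [(s, e) for s, e in runs if e - s >= w_min]

    split: list[tuple[int, int]] = []
    for s, e in runs:
        length = e - s
        k = -(-length // w_max)  # ceil
        bounds = np.linspace(s, e, k + 1).round().astype(int)
        split.extend(
            (int(bounds[i]), int(bounds[i + 1]))
            for i in range(k)
            if bounds[i + 1] - bounds[i] >= w_min
        )
    runs = split

    motifs = [
        Motif(
            index=0,
            start=s + 1,
            width=e - s,
            column_scores=cons[s:e].copy(),
            sub_pssm=scores_x[s:e].copy(),
        )
        for s, e in runs
    ]
    if len(motifs) > max_motifs:
        motifs = sorted(motifs, key=lambda m: -m.mean_conservation)[:max_motifs]
        motifs.sort(key=lambda m: m.start)
    for i, m in enumerate(motifs, start=1):
        m.index = i
    spacing = [
        motifs[i + 1].start - (motifs[i].end + 1) for i in range(len(motifs) - 1)
    ]
    return MotifSet(family_id, motifs, spacing)


def _scan_motif(motif: Motif, query_idx: np.ndarray) -> MotifHit | None:
    w = motif.width
    m = query_idx.shape[0]
    if m < w:
        return None
    best = -np.inf
    best_pos = 0
    rows = np.arange(w)
    for off in range(m - w + 1):
        s = float(motif.sub_pssm[rows, query_idx[off : off + w]].sum())
        if s > best:
            best = s
            best_pos = off
    return MotifHit(motif.index, best_pos + 1, best)


def motif_assign(
    motifs: MotifSet,
    query: ProteinSequence,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    bits_per_column: float = DEFAULT_BITS_PER_COLUMN,
    spacing_tolerance: float = DEFAULT_SPACING_TOLERANCE,
) -> MotifAssignment:
    """Decide family membership from ungapped motif matches.

    A motif is found if its best ungapped window scores at least
    ``bits_per_column * width`` bits. The query is assigned iff (a) at
    least ``ceil(min_fraction * n_motifs)`` motifs are found, (b) the
    found motifs occur in family order, and (c) each consecutive found
    pair's start-to-start distance in the query is within
    ``(1 +/- spacing_tolerance)`` of the family's.
    """
    if len(motifs) == 0:
        raise ValueError("empty MotifSet")
    idx = encode(query.residues)
    found: list[MotifHit] = []
    for motif in motifs.motifs:
        hit = _scan_motif(motif, idx)
        if hit is not None and hit.score >= bits_per_column * motif.width:
            found.append(hit)
    total = sum(h.score for h in found)
    needed = math.ceil(min_fraction * len(motifs))
    if len(found) < needed:
        return MotifAssignment(False, found, total)
    positions = [h.query_start for h in found]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        return MotifAssignment(False, found, total)
    by_index = {m.index: m for m in motifs.motifs}
    for h1, h2 in zip(found, found[1:]):
        fam_dist = by_index[h2.motif_index].start - by_index[h1.motif_index].start
        q_dist = h2.query_start - h1.query_start
        lo = (1.0 - spacing_tolerance) * fam_dist
        hi = (1.0 + spacing_tolerance) * fam_dist
        if not lo <= q_dist <= hi:
            return MotifAssignment(False, found, total)
    return MotifAssignment(True, found, total)
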