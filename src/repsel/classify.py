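"""Why a member escaped its family profile: the unrecognized-sequence taxonomy.

Members that neither engine recognizes are explained, in fixed precedence
order, as one of:

1. ``partial`` - shorter than 60% of the family's mean length (fragments
   and partial domains);
2. ``low_complexity`` - more than 30% of residues inside SEG-style
   low-complexity segments;
3. ``composition_bias`` - at least one predicted transmembrane-like
   hydrophobic stretch, or more than 75% polar residues;
4. ``outlier`` - divergence ratio below 0.8, i.e. the member's mean
   identity to the 50% non-redundant set is less than 80% of that set's
   own mean pairwise identity;
5. ``unexplained`` otherwise.

The precedence mirrors the survivor-style accounting of the source
protocol: each sequence gets exactly one category, but every record keeps
all five measurements so the decision can be re-derived.

Low complexity uses windowed Shannon entropy (SEG-style trigger/extend
thresholds, no final minimization step). Transmembrane detection is a
declared hydropathy stand-in (Kyte-Doolittle sliding mean), not a
reimplementation of dedicated TM predictors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._scoring import POLAR_RESIDUES, kd_values
from .pairwise import IdentityMatrix
from .seqio import FamilyDataset, ProteinSequence

CATEGORY_PARTIAL = "partial"
CATEGORY_LOWCOMP = "low_complexity"
CATEGORY_COMPBIAS = "composition_bias"
CATEGORY_OUTLIER = "outlier"
CATEGORY_UNEXPLAINED = "unexplained"

PARTIAL_LENGTH_RATIO = 0.60
LOWCOMP_FRACTION = 0.30
POLAR_FRACTION = 0.75
OUTLIER_RATIO = 0.80

SEG_WINDOW = 12
SEG_K2_TRIGGER = 2.2
SEG_K2_EXTEND = 2.5
SEG_MIN_LEN = 10

TM_WINDOW = 19
TM_THRESHOLD = 1.6


@dataclass
class ClassificationRecord:
    member_id: str
    category: str
    length_ratio: float
    lowcomp_fraction: float
    tm_segments: int
    polar_fraction: float
    divergence_ratio: float


def window_entropy(counts: dict[str, int], width: int) -> float:
    """Shannon entropy K2 of one window's residue composition (bits)."""
    h = 0.0
    for n in counts.values():
        if n:
            p = n / width
            h -= p * math.log2(p)
    return h


def _window_entropies(seq: str, window: int) -> np.ndarray:
    """K2 for every window start (rolling composition update)."""
    n = len(seq)
    out = np.empty(n - window + 1)
    counts: dict[str, int] = {}
    for ch in seq[:window]:
        counts[ch] = counts.get(ch, 0) + 1
    out[0] = window_entropy(counts, window)
    for i in range(1, n - window + 1):
        old, new = seq[i - 1], seq[i + window - 1]
        counts[old] -= 1
        if counts[old] == 0:
            del counts[old]
        counts[new] = counts.get(new, 0) + 1
        out[i] = window_entropy(counts, window)
    return out


def seg_low_complexity(
    seq: ProteinSequence | str,
    window: int = SEG_WINDOW,
    k2_trigger: float = SEG_K2_TRIGGER,
    k2_extend: float = SEG_K2_EXTEND,
    min_len: int = SEG_MIN_LEN,
) -> list[tuple[int, int]]:
    """SEG-style low-complexity segments as 1-based inclusive intervals.

    Windows with K2 <= ``k2_trigger`` seed segments; each seed extends
    over the contiguous block of windows with K2 <= ``k2_extend`` around
    it. Overlapping segments merge; segments shorter than ``min_len`` are
    discarded.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < window:
        return []
    k2 = _window_entropies(residues, window)
    trigger = k2 <= k2_trigger
    extend = k2 <= k2_extend
    if not trigger.any():
        return []

    nw = len(k2)
    segments: list[tuple[int, int]] = []  # 0-based inclusive residue spans
    i = 0
    while i < nw:
        if not trigger[i]:
            i += 1
            continue
        lo = i
        while lo > 0 and extend[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < nw and extend[hi + 1]:
            hi += 1
        segments.append((lo, hi + window - 1))
        i = hi + 1

    merged: list[list[int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        (s + 1, e + 1) for s, e in merged if (e - s + 1) >= min_len
    ]


def lowcomp_fraction(seq: ProteinSequence, **kwargs) -> float:
    """Fraction of residues inside low-complexity segments."""
    segments = seg_low_complexity(seq, **kwargs)
    covered = sum(e - s + 1 for s, e in segments)
    return covered / seq.length


def tm_segments(
    seq: ProteinSequence | str,
    window: int = TM_WINDOW,
    threshold: float = TM_THRESHOLD,
) -> int:
    """Count of transmembrane-like hydrophobic stretches.

    Kyte-Doolittle hydropathy averaged over a sliding window; maximal
    runs of window starts with mean above ``threshold``; runs separated
    by less than half a window merge into one segment.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if n < window:
        return 0
    kd = kd_values(residues)
    csum = np.concatenate([[0.0], np.cumsum(kd)])
    means = (csum[window:] - csum[:-window]) / window
    above = means > threshold
    if not above.any():
        return 0
    # maximal runs over window starts
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    merged = [runs[0]]
    min_gap = window // 2
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return len(merged)


def polar_fraction(seq: ProteinSequence) -> float:
    return sum(1 for c in seq.residues if c in POLAR_RESIDUES) / seq.length


def divergence_ratio(
    member_id: str, nr50: FamilyDataset, matrix: IdentityMatrix
) -> float:
    """Member's mean identity to the 50% set over that set's mean identity.

    The denominator excludes pairs involving the member itself; values
    below :data:`OUTLIER_RATIO` mark the member as significantly far from
    the rest of the family.
    """
    if len(nr50) < 3:
        raise ValueError("divergence ratio needs >= 3 non-redundant sequences")
    others = [i for i in nr50.ids if i != member_id]
    numerator = float(np.mean([matrix.value(member_id, o) for o in others]))
    pair_vals = [
        matrix.value(others[i], others[j])
        for i in range(len(others))
        for j in range(i + 1, len(others))
    ]
    denominator = float(np.mean(pair_vals))
    if denominator == 0:
        raise ValueError("degenerate family: zero mean pairwise identity")
    return numerator / denominator


def category_from_measurements(
    length_ratio_: float,
    lowcomp_fraction_: float,
    tm_segments_: int,
    polar_fraction_: float,
    divergence_ratio_: float,
) -> str:
    """Apply the precedence rule to stored measurements (first match wins)."""
    if length_ratio_ < PARTIAL_LENGTH_RATIO:
        return CATEGORY_PARTIAL
    if lowcomp_fraction_ > LOWCOMP_FRACTION:
        return CATEGORY_LOWCOMP
    if tm_segments_ >= 1 or polar_fraction_ > POLAR_FRACTION:
        return CATEGORY_COMPBIAS
    if divergence_ratio_ < OUTLIER_RATIO:
        return CATEGORY_OUTLIER
    return CATEGORY_UNEXPLAINED


def classify_unrecognized(
    unrecognized: list[str],
    family: FamilyDataset,
    nr50: FamilyDataset,
    matrix: IdentityMatrix,
) -> list[ClassificationRecord]:
    """Classify members the representative profile failed to recognize."""
    unknown = set(unrecognized) - set(family.ids)
    if unknown:
        raise ValueError(f"ids not in family: {sorted(unknown)}")
    mean_len = family.mean_length
    records = []
    for member_id in unrecognized:
        seq = family.get(member_id)
        lr = seq.length / mean_len
        lf = lowcomp_fraction(seq)
        tm = tm_segments(seq)
        pf = polar_fraction(seq)
        dr = divergence_ratio(member_id, nr50, matrix)
        records.append(
            ClassificationRecord(
                member_id=member_id,
                category=category_from_measurements(lr, lf, tm, pf, dr),
                length_ratio=lr,
                lowcomp_fraction=lf,
                tm_segments=tm,
                polar_fraction=pf,
                divergence_ratio=dr,
            )
        )
    return records


def classification_to_tsv(
    records: list[ClassificationRecord], path: str | Path
) -> Path:
    cols = [
        "member_id", "category", "length_ratio", "lowcomp_fraction",
        "tm_segments", "polar_fraction", "divergence_ratio",
    ]
    rows = [
        {
            "member_id": r.member_id,
            "category": r.category,
            "length_ratio": round(r.length_ratio, 4),
            "lowcomp_fraction": round(r.lowcomp_fraction, 4),
            "tm_segments": r.tm_segments,
            "polar_fraction": round(r.polar_fraction, 4),
            "divergence_ratio": round(r.divergence_ratio, 4),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return Path(path)
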