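"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from the problem definition, not
from the package's code paths: exhaustive enumeration instead of dynamic
programming, per-window recomputation instead of rolling updates.
"""
from __future__ import annotations

import math
from collections import Counter


def score_alignment(
    row_a: str,
    row_b: str,
    sub,
    lookup,
    gap_open: float = 11.0,
    gap_ext: float = 1.0,
) -> float:
    """Score two gapped rows: substitution sum minus affine gap-run costs.

    Every maximal gap run (terminal runs included) costs
    ``gap_open + gap_ext * run_length``.
    """
    total = 0.0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            total += sub[lookup[x], lookup[y]]
    for row in (row_a, row_b):
        run = 0
        for ch in row + "$":
            if ch == "-":
                run += 1
            elif run:
                total -= gap_open + gap_ext * run
                run = 0
    return total


def enumerate_best_score(
    a: str,
    b: str,
    sub,
    lookup,
    gap_open: float = 11.0,
    gap_ext: float = 1.0,
) -> float:
    """Optimal global affine-gap score by exhaustive move enumeration."""
    n, m = len(a), len(b)
    best = [-math.inf]

    def rec(i: int, j: int, state: str, score: float) -> None:
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "M", score + sub[lookup[a[i]], lookup[b[j]]])
        if i < n:
            cost = gap_ext if state == "A" else gap_open + gap_ext
            rec(i + 1, j, "A", score - cost)
        if j < m:
            cost = gap_ext if state == "B" else gap_open + gap_ext
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, "", 0.0)
    return best[0]


def window_k2(window: str) -> float:
    """Shannon entropy of one window's composition, recomputed from scratch."""
    w = len(window)
    h = 0.0
    for n in Counter(window).values():
        p = n / w
        h -= p * math.log2(p)
    return h


def seg_segments_bruteforce(
    seq: str,
    window: int = 12,
    k2_trigger: float = 2.2,
    k2_extend: float = 2.5,
    min_len: int = 10,
) -> list[tuple[int, int]]:
    """Low-complexity segments via per-window recomputation.

    Connected blocks of extendable windows (K2 <= k2_extend) containing
    at least one trigger window (K2 <= k2_trigger) become segments
    spanning the residues of their windows; overlapping or touching
    segments merge; short segments are dropped.
    """
    n = len(seq)
    if n < window:
        return []
    k2 = [window_k2(seq[i : i + window]) for i in range(n - window + 1)]
    nw = len(k2)
    # connected components of extendable windows
    components: list[tuple[int, int]] = []
    i = 0
    while i < nw:
        if k2[i] <= k2_extend:
            j = i
            while j + 1 < nw and k2[j + 1] <= k2_extend:
                j += 1
            components.append((i, j))
            i = j + 1
        else:
            i += 1
    spans = [
        (lo, hi + window - 1)
        for lo, hi in components
        if any(k2[w] <= k2_trigger for w in range(lo, hi + 1))
    ]
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len]


def tm_count_bruteforce(
    seq: str, kd_scale: dict, window: int = 19, threshold: float = 1.6
) -> int:
    """Hydrophobic segment count via plain per-window means."""
    n = len(seq)
    if n < window:
        return 0
    above = []
    for i in range(n - window + 1):
        mean = sum(kd_scale[c] for c in seq[i : i + window]) / window
        above.append(mean > threshold)
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        if not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    if not runs:
        return 0
    count = 1
    for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
        if s2 - e1 - 1 >= window // 2:
            count += 1
    return count
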