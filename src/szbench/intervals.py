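"""Half-open interval algebra on the global time axis.

All times are float seconds with the origin at the start of the first
recording file.  An interval set is a normalized tuple of ``(start, end)``
pairs: sorted, pairwise disjoint, every ``end > start``.  Degenerate or
inverted pairs vanish under :func:`normalize`, which keeps downstream gap
arithmetic (clipping preictal windows around missing data, subtracting
ictal spans) free of special cases.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

Interval = Tuple[float, float]
IntervalSet = Tuple[Interval, ...]


def normalize(intervals: Iterable[Sequence[float]]) -> IntervalSet:
    """Sort, drop empty intervals, and merge overlapping/abutting ones."""
    items = sorted((float(a), float(b)) for a, b in intervals if b > a)
    merged: list[Interval] = []
    for a, b in items:
        if merged and a <= merged[-1][1]:
            prev_a, prev_b = merged[-1]
            merged[-1] = (prev_a, max(prev_b, b))
        else:
            merged.append((a, b))
    return tuple(merged)


def total_length(intervals: Iterable[Sequence[float]]) -> float:
    return sum(b - a for a, b in normalize(intervals))


def intersect(xs: Iterable[Sequence[float]], ys: Iterable[Sequence[float]]) -> IntervalSet:
    """Pairwise intersection of two interval sets."""
    xs_n, ys_n = normalize(xs), normalize(ys)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs_n) and j < len(ys_n):
        a = max(xs_n[i][0], ys_n[j][0])
        b = min(xs_n[i][1], ys_n[j][1])
        if b > a:
            out.append((a, b))
        # advance whichever interval ends first
        if xs_n[i][1] <= ys_n[j][1]:
            i += 1
        else:
            j += 1
    return tuple(out)


def subtract(xs: Iterable[Sequence[float]], ys: Iterable[Sequence[float]]) -> IntervalSet:
    """Set difference xs \\ ys."""
    xs_n, ys_n = normalize(xs), normalize(ys)
    out: list[Interval] = []
    for a, b in xs_n:
        cur = a
        for ya, yb in ys_n:
            if yb <= cur:
                continue
            if ya >= b:
                break
            if ya > cur:
                out.append((cur, ya))
            cur = max(cur, yb)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return tuple(out)


def union(xs: Iterable[Sequence[float]], ys: Iterable[Sequence[float]]) -> IntervalSet:
    return normalize(list(xs) + list(ys))


def contains(intervals: Iterable[Sequence[float]], start: float, end: float) -> bool:
    """True iff the half-open interval [start, end) lies inside the set."""
    if end <= start:
        return True  # empty interval is inside everything
    for a, b in normalize(intervals):
        if a <= start and end <= b:
            return True
    return False


def contains_point(intervals: Iterable[Sequence[float]], t: float) -> bool:
    return any(a <= t < b for a, b in normalize(intervals))
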