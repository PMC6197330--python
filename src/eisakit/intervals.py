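"""Half-open interval arithmetic on ``(start, end)`` pairs.

All coordinates are 0-based, half-open ``[start, end)`` base-pair positions.
These helpers back the region indexing in :mod:`eisakit.counting` and the
genome generator; they are deliberately tiny and fully deterministic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or touching intervals are merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: Sequence[Interval], cuts: Iterable[Interval]) -> list[Interval]:
    """Bases in ``base`` not covered by ``cuts`` (both need not be merged)."""
    base_m = merge(base)
    cuts_m = merge(cuts)
    out: list[Interval] = []
    for bs, be in base_m:
        cur = bs
        for cs, ce in cuts_m:
            if ce <= cur or cs >= be:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= be:
                break
        if cur < be:
            out.append((cur, be))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    am, bm = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if s < e:
            out.append((s, e))
        if am[i][1] <= bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlap_length(intervals: Sequence[Interval], start: int, end: int) -> int:
    return total_length(intersect(intervals, [(start, end)]))


def fully_contained(intervals: Sequence[Interval], start: int, end: int) -> bool:
    """True if [start, end) lies entirely within the union of ``intervals``."""
    return overlap_length(intervals, start, end) == end - start
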