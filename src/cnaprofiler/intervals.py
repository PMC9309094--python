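"""Half-open integer interval set algebra.

All functions operate on lists of ``(start, end)`` tuples with ``end > start``,
interpreted as 0-based half-open genomic intervals on a single chromosome.
Canonical form is sorted, non-overlapping and non-touching; :func:`merge`
produces it and every other function returns it.

This tiny algebra is the computational core of the genomic Jaccard
similarity: base-pair intersection and union lengths of aberrant territory.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and coalesce intervals; touching intervals ([0,5),[5,9)) merge."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two canonical interval sets (linear sweep)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    return merge(list(a) + list(b))


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Bases in ``a`` not in ``b``; both canonical."""
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def coverage_within(intervals: Sequence[Interval], start: int, end: int) -> int:
    """Base count of ``intervals`` falling inside [start, end)."""
    return total_length(intersect(list(intervals), [(start, end)]))
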