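"""Shared interval algebra.

All coordinates in the package are 0-based half-open on a named sequence;
the helpers here operate on plain ``(start, end)`` tuples so callers can
work either with bare coordinates or with :class:`GenomicInterval`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_coords(coords: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge ``(start, end)`` pairs into disjoint sorted intervals."""
    items = sorted((s, e) for s, e in coords if e > s)
    out: list[tuple[int, int]] = []
    for s, e in items:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def interval_union(
    intervals: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], int]:
    """Union of intervals on a single chromosome.

    Returns the disjoint sorted intervals covering exactly the union and
    the total number of covered bases. All inputs must lie on one
    chromosome; mixing chromosomes is an error (union across chromosomes
    has no single-coordinate meaning).
    """
    if not intervals:
        return [], 0
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        a, b, *_ = sorted(chroms)
        raise ValueError(f"interval_union on mixed chromosomes: {a!r} vs {b!r}")
    chrom = intervals[0].chrom
    merged = merge_coords((iv.start, iv.end) for iv in intervals)
    out = [GenomicInterval(chrom, s, e) for s, e in merged]
    return out, sum(e - s for s, e in merged)


def subtract_coords(
    base: Sequence[tuple[int, int]], remove: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference base \\ remove on half-open coordinate pairs."""
    base_m = merge_coords(base)
    rem_m = merge_coords(remove)
    out: list[tuple[int, int]] = []
    ri = 0
    for s, e in base_m:
        cur = s
        while ri < len(rem_m) and rem_m[ri][1] <= cur:
            ri += 1
        j = ri
        while j < len(rem_m) and rem_m[j][0] < e:
            rs, re = rem_m[j]
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if re >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_coords(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two coordinate-pair sets."""
    am = merge_coords(a)
    bm = merge_coords(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if s < e:
            out.append((s, e))
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement_coords(
    length: int, intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Complement of intervals within ``[0, length)``."""
    return subtract_coords([(0, length)], intervals)
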