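"""Small-RNA population statistics.

Length profiles of mapped 18-32 nt reads, positional nucleotide
composition (the 1U bias of primary piRNAs and the 10A ping-pong
signature), and the distribution of 5' overlaps between opposite-strand
read pairs, whose excess at exactly 10 nt is the ping-pong signature of
slicer-dependent piRNA amplification.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_NT = ("A", "C", "G", "U")
PIRNA_RANGE = (27, 30)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped small-RNA read.

    ``sequence`` is in read (5'->3') orientation; U and T are
    equivalent. ``count`` carries the multiplicity of identical reads.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"read at {self.chrom}:{self.start}-{self.end}: span "
                f"{self.end - self.start} != sequence length {len(self.sequence)}"
            )
        if self.count < 1:
            raise ValueError("count must be >= 1")
        bad = set(self.sequence.upper()) - set("ACGUTN")
        if bad:
            raise ValueError(f"bad nucleotide(s) {sorted(bad)} in read sequence")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (base position)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LengthHistogram:
    """Per-length read fractions, per replicate, with a mean track."""

    lengths: list[int]
    per_replicate: pd.DataFrame  # index = length, one column per replicate
    mean: pd.Series  # mean of the per-replicate fractions


class PositionFreqMatrix:
    """Count-weighted nucleotide frequencies at read positions 1..k."""

    def __init__(self, counts: np.ndarray):
        # counts: shape (4, k), rows ordered A, C, G, U
        self.counts = counts
        denom = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequencies = np.where(denom > 0, counts / denom, 0.0)

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    def frequency(self, nt: str, position: int) -> float:
        """Frequency of ``nt`` at 1-based read position."""
        return float(self.frequencies[_NT.index(nt.upper()), position - 1])

    @property
    def u1_fraction(self) -> float:
        return self.frequency("U", 1)

    @property
    def a10_fraction(self) -> float:
        return self.frequency("A", 10)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies.T, index=range(1, self.k + 1), columns=_NT
        )


@dataclass
class OverlapDistribution:
    """Counts of opposite-strand pairs by exact 5' overlap length."""

    counts: pd.Series  # index k = 1..k_max

    @property
    def argmax(self) -> int:
        return int(self.counts.idxmax())

    def z_score(self, k: int = 10) -> float:
        """z of bin k against mean/sd of the other bins."""
        others = self.counts.drop(index=k)
        sd = float(others.std(ddof=1))
        if sd == 0:
            return float("nan")
        return (float(self.counts.loc[k]) - float(others.mean())) / sd


def filter_by_length(
    reads: Sequence[AlignedRead], lo: int = 18, hi: int = 32
) -> list[AlignedRead]:
    """Keep reads with lo <= length <= hi (inclusive bounds)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return [r for r in reads if lo <= r.length <= hi]


def length_histogram(
    replicates: Sequence[Sequence[AlignedRead]],
    lo: int = 18,
    hi: int = 32,
) -> LengthHistogram:
    """Per-replicate length fractions and their across-replicate mean.

    The mean averages fractions, not pooled counts, so each replicate
    contributes equally regardless of depth. Replicates with zero reads
    are excluded from the mean with a warning.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    lengths = list(range(lo, hi + 1))
    cols = {}
    for idx, reads in enumerate(replicates):
        counts = pd.Series(0.0, index=lengths)
        total = 0
        for r in reads:
            if lo <= r.length <= hi:
                counts.loc[r.length] += r.count
                total += r.count
        if total == 0:
            log.warning("replicate %d has no reads in [%d, %d]; excluded "
                        "from the mean", idx, lo, hi)
            continue
        cols[f"rep{idx + 1}"] = counts / total
    per_rep = pd.DataFrame(cols, index=lengths)
    if per_rep.empty or per_rep.shape[1] == 0:
        raise ValueError("all replicates are empty")
    return LengthHistogram(
        lengths=lengths, per_replicate=per_rep, mean=per_rep.mean(axis=1)
    )


def position_frequency_matrix(
    reads: Sequence[AlignedRead], k: int = 10
) -> PositionFreqMatrix:
    """Count-weighted per-position composition in 5'->3' orientation.

    T is normalized to U; N never enters a position's denominator; reads
    shorter than k contribute only to positions up to their length.
    """
    if not reads:
        raise ValueError("position_frequency_matrix on empty read set")
    counts = np.zeros((4, k))
    index = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
    for r in reads:
        seq = r.sequence.upper()
        for pos in range(min(k, len(seq))):
            i = index.get(seq[pos])
            if i is not None:
                counts[i, pos] += r.count
    return PositionFreqMatrix(counts)


def five_prime_overlap_distribution(
    reads: Sequence[AlignedRead],
    k_max: int = 25,
    weight_by_count: bool = True,
) -> OverlapDistribution:
    """Exact 5'-overlap length distribution of opposite-strand pairs.

    For a plus read p and a minus read m on the same chromosome the 5'
    end of p is ``start_p`` and the 5' end of m is ``end_m - 1``; their
    5' overlap is ``k = end_m - start_p`` bases. A pair contributes
    count_p * count_m to bin k when 1 <= k <= min(len_p, len_m, k_max).
    """
    bins = pd.Series(0.0, index=range(1, k_max + 1))
    by_chrom_plus: dict[str, list[AlignedRead]] = {}
    by_chrom_minus: dict[str, list[AlignedRead]] = {}
    for r in reads:
        (by_chrom_plus if r.strand == "+" else by_chrom_minus).setdefault(
            r.chrom, []
        ).append(r)
    for chrom, plus in by_chrom_plus.items():
        minus = by_chrom_minus.get(chrom)
        if not minus:
            continue
        minus.sort(key=lambda r: r.end)
        ends = [m.end for m in minus]
        for p in plus:
            lo = bisect_left(ends, p.start + 1)
            hi = bisect_right(ends, p.start + k_max)
            for m in minus[lo:hi]:
                k = m.end - p.start
                if k <= min(p.length, m.length):
                    w = p.count * m.count if weight_by_count else 1
                    bins.loc[k] += w
    return OverlapDistribution(counts=bins)
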