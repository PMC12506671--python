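"""piRNA cluster calling, merging and ranking.

A simple read-density caller stands in for dedicated cluster-annotation
tools: maximal runs of fixed-size windows holding enough piRNA-sized
reads become candidate clusters, oriented by strand bias. Adjacent
same-orientation clusters closer than 5 kb are merged, and the merged
list is ranked by RPM with the cumulative fraction of cluster-mapping
piRNAs (the "top N clusters produce 90% of piRNAs" statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .smallrna import AlignedRead

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 5_000


@dataclass(frozen=True)
class PiCluster:
    chrom: str
    start: int
    end: int
    orientation: str  # plus | minus | bidirectional
    read_count: float
    rpm: float = 0.0
    rank: int | None = None
    cumulative_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("cluster start must be < end")
        if self.orientation not in ("plus", "minus", "bidirectional"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def call_clusters_density(
    reads: Sequence[AlignedRead],
    window: int = 1_000,
    min_reads: int = 10,
    min_strand_bias: float = 0.75,
) -> list[PiCluster]:
    """Call candidate clusters as dense runs of read-start windows.

    Reads are binned by 5'-start window; maximal runs of consecutive
    windows each holding >= min_reads (multiplicity-weighted) become one
    cluster spanning from the first to the last read in the run.
    Orientation is plus/minus when >= min_strand_bias of the run's reads
    sit on one strand, else bidirectional. Input reads should already be
    length-filtered to the piRNA range.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_window: dict[tuple[str, int], list[AlignedRead]] = {}
    for r in reads:
        by_window.setdefault((r.chrom, r.start // window), []).append(r)
    dense = {
        key for key, rs in by_window.items()
        if sum(r.count for r in rs) >= min_reads
    }
    clusters: list[PiCluster] = []
    for chrom in sorted({c for c, _ in dense}):
        wins = sorted(w for c, w in dense if c == chrom)
        run: list[int] = []
        for w in wins + [None]:  # type: ignore[list-item]
            if run and (w is None or w != run[-1] + 1):
                run_reads = [
                    r for win in run for r in by_window[(chrom, win)]
                ]
                total = sum(r.count for r in run_reads)
                plus = sum(r.count for r in run_reads if r.strand == "+")
                if plus / total >= min_strand_bias:
                    orientation = "plus"
                elif (total - plus) / total >= min_strand_bias:
                    orientation = "minus"
                else:
                    orientation = "bidirectional"
                clusters.append(
                    PiCluster(
                        chrom=chrom,
                        start=min(r.start for r in run_reads),
                        end=max(r.end for r in run_reads),
                        orientation=orientation,
                        read_count=total,
                    )
                )
                run = []
            if w is not None:
                run.append(w)
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def merge_adjacent(
    clusters: Sequence[PiCluster],
    max_gap: int = DEFAULT_MAX_GAP,
    merge_bidirectional: bool = False,
) -> list[PiCluster]:
    """Merge consecutive same-orientation clusters < max_gap apart.

    The gap is next.start - prev.end with a strict '<' comparison; read
    counts add. Bidirectional clusters never merge with stranded ones
    unless ``merge_bidirectional`` is set. Overlapping clusters with
    conflicting orientation are left unmerged with a warning. The result
    is a fixed point: no further merge is possible.
    """
    ordered = sorted(clusters, key=lambda c: (c.chrom, c.start, c.end))
    out: list[PiCluster] = []
    for c in ordered:
        prev = out[-1] if out else None
        if prev is not None and prev.chrom == c.chrom:
            gap = c.start - prev.end
            same = prev.orientation == c.orientation and (
                merge_bidirectional or prev.orientation != "bidirectional"
            )
            if gap < max_gap:
                if same:
                    out[-1] = replace(
                        prev,
                        end=max(prev.end, c.end),
                        read_count=prev.read_count + c.read_count,
                    )
                    continue
                if gap < 0:
                    log.warning(
                        "overlapping clusters with conflicting orientation at "
                        "%s:%d-%d / %d-%d left unmerged",
                        c.chrom, prev.start, prev.end, c.start, c.end,
                    )
        out.append(c)
    return out


def rank_and_cumulative(
    clusters: Sequence[PiCluster], total_mapped_reads: float
) -> list[PiCluster]:
    """Rank clusters by RPM and attach the cumulative fraction.

    RPM = read_count / (total_mapped_reads / 1e6). The cumulative
    fraction is taken over the sum of cluster RPM values (the fraction
    of cluster-mapping piRNAs, not of all mapped reads). Ties in RPM
    order by (chrom, start).
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if not clusters:
        raise ValueError("no clusters to rank")
    scale = total_mapped_reads / 1e6
    ranked = sorted(
        (replace(c, rpm=c.read_count / scale) for c in clusters),
        key=lambda c: (-c.rpm, c.chrom, c.start),
    )
    total_rpm = sum(c.rpm for c in ranked)
    cum = 0.0
    out = []
    for i, c in enumerate(ranked, start=1):
        cum += c.rpm
        out.append(
            replace(c, rank=i, cumulative_fraction=cum / total_rpm)
        )
    return out


def top_n_for_fraction(ranked: Sequence[PiCluster], f: float) -> int:
    """Smallest N such that the top-N cumulative fraction >= f."""
    if not ranked:
        raise ValueError("top_n_for_fraction on an empty cluster list")
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    for c in ranked:
        if c.cumulative_fraction is None:
            raise ValueError("clusters must come from rank_and_cumulative")
        if c.cumulative_fraction >= f - 1e-12:
            return c.rank  # type: ignore[return-value]
    return ranked[-1].rank  # type: ignore[return-value]
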