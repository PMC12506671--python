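"""Annotation-quality and assembly statistics.

Computes the descriptive statistics used to benchmark a de novo gene
annotation — transcript/gene counts, pooled exon and intron statistics,
the monoexonic ratio, UTR completeness, genome coverage fractions — and
assembly contiguity metrics (Nx/Lx).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import merge_coords


@dataclass
class Transcript:
    """One transcript: sorted exon intervals plus CDS and UTR presence."""

    id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    has_utr5: bool = False
    has_utr3: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def is_utr_complete(self) -> bool:
        return self.has_utr5 and self.has_utr3


@dataclass
class GeneModel:
    """A gene with its transcripts; the substrate of annotation metrics."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        """The gene's own interval (already min/max over transcripts
        when built without an explicit gene feature)."""
        return (self.start, self.end)


@dataclass
class AnnotationStats:
    n_genes: int
    n_transcripts: int
    n_monoexonic: int
    monoexonic_ratio_percent: float
    mean_exons_per_transcript: float
    mean_introns_per_transcript: float
    mean_exon_length: float
    mean_intron_length: float
    n_utr_complete: int
    gene_span_coverage_percent: float | None = None
    cds_coverage_percent: float | None = None


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    nx: dict[int, int]
    lx: dict[int, int]


def monoexonic_ratio(n_monoexonic: int, n_transcripts: int) -> float:
    """Monoexonic-to-multiexonic transcript ratio, in percent.

    100 * n_monoexonic / (n_transcripts - n_monoexonic), reported rounded
    half-up to 2 decimals. This is the annotation-quality benchmark that
    compares single-exon transcripts against the rest of the annotation.
    """
    if n_monoexonic < 0:
        raise ValueError("n_monoexonic must be >= 0")
    if n_transcripts <= n_monoexonic:
        raise ValueError(
            "n_transcripts must exceed n_monoexonic "
            f"(got {n_transcripts} <= {n_monoexonic})"
        )
    ratio = decimal.Decimal(100 * n_monoexonic) / decimal.Decimal(
        n_transcripts - n_monoexonic
    )
    return float(ratio.quantize(decimal.Decimal("0.01"), decimal.ROUND_HALF_UP))


def transcript_stats(models: Sequence[GeneModel]) -> AnnotationStats:
    """Pooled annotation statistics over all transcripts.

    Mean exon/intron lengths pool every exon/intron across transcripts
    (total bp / total count), not per-transcript means of means.
    """
    transcripts = [t for g in models for t in g.transcripts]
    if not transcripts:
        raise ValueError("no transcripts in the supplied gene models")
    n_tx = len(transcripts)
    n_mono = sum(1 for t in transcripts if t.is_monoexonic)
    exon_lengths = [e - s for t in transcripts for s, e in t.exons]
    intron_lengths = [e - s for t in transcripts for s, e in t.introns]
    n_exons = len(exon_lengths)
    n_introns = len(intron_lengths)
    ratio = monoexonic_ratio(n_mono, n_tx) if n_mono < n_tx else float("nan")
    return AnnotationStats(
        n_genes=len(models),
        n_transcripts=n_tx,
        n_monoexonic=n_mono,
        monoexonic_ratio_percent=ratio,
        mean_exons_per_transcript=n_exons / n_tx,
        mean_introns_per_transcript=n_introns / n_tx,
        mean_exon_length=sum(exon_lengths) / n_exons,
        mean_intron_length=(
            sum(intron_lengths) / n_introns if n_introns else 0.0
        ),
        n_utr_complete=sum(1 for t in transcripts if t.is_utr_complete),
    )


def genome_coverage(
    models: Sequence[GeneModel], genome_length: int
) -> tuple[float, float]:
    """Percent of the genome covered by gene spans and by CDS.

    Overlapping features count once (union semantics, per chromosome).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    spans: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for g in models:
        if g.end > genome_length:
            raise ValueError(
                f"gene {g.id} ends at {g.end}, beyond genome length {genome_length}"
            )
        spans.setdefault(g.chrom, []).append(g.span)
        for t in g.transcripts:
            cds.setdefault(g.chrom, []).extend(t.cds)
    span_bp = sum(
        e - s for ivs in spans.values() for s, e in merge_coords(ivs)
    )
    cds_bp = sum(e - s for ivs in cds.values() for s, e in merge_coords(ivs))
    return 100.0 * span_bp / genome_length, 100.0 * cds_bp / genome_length


def nx_lx(lengths: Iterable[int], x: int = 50) -> tuple[int, int]:
    """Assembly Nx/Lx.

    Nx is the sequence length at which the cumulative sum of
    descending-sorted lengths first reaches >= x% of the total; Lx is the
    number of sequences needed to reach it.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("nx_lx on an empty length list")
    if any(l <= 0 for l in lens):
        raise ValueError("sequence lengths must be positive")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    target = x / 100.0 * sum(lens)
    cum = 0
    for i, l in enumerate(lens, start=1):
        cum += l
        if cum >= target:
            return l, i
    raise AssertionError("unreachable: cumulative sum must reach the total")


def assembly_stats(
    lengths: Iterable[int], x_values: Sequence[int] = (50, 90)
) -> AssemblyStats:
    lens = list(lengths)
    nx: dict[int, int] = {}
    lx: dict[int, int] = {}
    for x in x_values:
        nx[x], lx[x] = nx_lx(lens, x)
    return AssemblyStats(
        n_sequences=len(lens), total_length=sum(lens), nx=nx, lx=lx
    )
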