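"""Telomeric-motif scanning and windowed feature-density tracks.

Tandem-repeat arrays are scanned for the telomeric motif (TTAGGG by
default) on both strands, classified as terminal or interstitial by
their distance to the chromosome ends (interstitial telomeric sequences
are relics of chromosome fusions), and compared against the genome
average GC%. Feature density tracks tile each chromosome with fixed
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .intervals import intersect_coords

DEFAULT_MOTIF = "TTAGGG"
DEFAULT_TERMINAL_WINDOW = 100_000
DEFAULT_GENOME_GC = 42.0

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class TandemArray:
    chrom: str
    start: int
    end: int
    sequence: str | None = None
    unit: str | None = None
    gc_percent: float | None = None
    motif_count_fwd: int = 0
    motif_count_rev: int = 0
    position_class: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("array start must be < end")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.gc_percent is None:
                self.gc_percent = gc_content(self.sequence)
        if self.gc_percent is not None and not 0 <= self.gc_percent <= 100:
            raise ValueError("gc_percent outside [0, 100]")


@dataclass
class DensityTrack:
    window: int
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, win_start, win_end, then one column per feature class


def gc_content(sequence: str) -> float:
    """GC percent over non-N bases; 0 for all-N or empty sequences."""
    seq = sequence.upper()
    denom = sum(1 for c in seq if c != "N")
    if denom == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / denom


def motif_count(sequence: str, motif: str = DEFAULT_MOTIF) -> tuple[int, int]:
    """Non-overlapping occurrences of the motif and its reverse complement.

    Both scans are greedy left-to-right; an empty sequence yields (0, 0).
    """
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 nt")
    seq = sequence.upper()

    def scan(m: str) -> int:
        count = 0
        pos = seq.find(m)
        while pos != -1:
            count += 1
            pos = seq.find(m, pos + len(m))
        return count

    return scan(motif.upper()), scan(reverse_complement(motif))


def classify_array_position(
    array: TandemArray,
    chrom_length: int,
    terminal_window: int = DEFAULT_TERMINAL_WINDOW,
) -> str:
    """``terminal`` if any part of the array lies within terminal_window
    of either chromosome end, else ``interstitial``."""
    if array.end > chrom_length:
        raise ValueError(
            f"array {array.chrom}:{array.start}-{array.end} extends beyond "
            f"chromosome length {chrom_length}"
        )
    if array.start < terminal_window or array.end > chrom_length - terminal_window:
        return "terminal"
    return "interstitial"


def gc_delta(array: TandemArray, genome_gc: float = DEFAULT_GENOME_GC) -> float:
    """Signed GC enrichment of the array over the genome average, in
    percentage points."""
    if array.gc_percent is None:
        raise ValueError(
            "array carries neither a sequence nor a precomputed GC percent"
        )
    return array.gc_percent - genome_gc


def annotate_arrays(
    arrays: Sequence[TandemArray],
    chrom_lengths: dict[str, int],
    motif: str = DEFAULT_MOTIF,
    terminal_window: int = DEFAULT_TERMINAL_WINDOW,
    genome_gc: float = DEFAULT_GENOME_GC,
) -> pd.DataFrame:
    """Full per-array report: motif counts, position class, GC delta."""
    rows = []
    for a in arrays:
        if a.chrom not in chrom_lengths:
            raise ValueError(f"array on unknown chromosome {a.chrom!r}")
        if a.sequence is not None:
            a.motif_count_fwd, a.motif_count_rev = motif_count(a.sequence, motif)
        a.position_class = classify_array_position(
            a, chrom_lengths[a.chrom], terminal_window
        )
        rows.append(
            {
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "motif_fwd": a.motif_count_fwd,
                "motif_rev": a.motif_count_rev,
                "position_class": a.position_class,
                "gc_percent": a.gc_percent,
                "gc_delta": (
                    gc_delta(a, genome_gc) if a.gc_percent is not None else None
                ),
            }
        )
    return pd.DataFrame(rows)


def window_density(
    features: Sequence[tuple[str, int, int, str]],
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
    mode: str = "fraction",
) -> DensityTrack:
    """Per-window feature density per class.

    ``features`` are (chrom, start, end, class) tuples. Windows tile
    each chromosome from position 0; the last window may be short. In
    ``fraction`` mode each cell is the fraction of window bases covered
    by that class (union within the class); in ``count`` mode it is the
    number of features whose start lies in the window.
    """
    if mode not in ("count", "fraction"):
        raise ValueError("mode must be 'count' or 'fraction'")
    classes = sorted({f[3] for f in features})
    per_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, start, end, cls in features:
        if chrom not in chrom_lengths:
            raise ValueError(f"feature on unknown chromosome {chrom!r}")
        per_chrom.setdefault(chrom, {}).setdefault(cls, []).append((start, end))
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for ws in range(0, length, window):
            we = min(ws + window, length)
            row: dict[str, object] = {
                "chrom": chrom, "win_start": ws, "win_end": we
            }
            for cls in classes:
                ivs = per_chrom.get(chrom, {}).get(cls, [])
                if mode == "count":
                    row[cls] = sum(1 for s, _ in ivs if ws <= s < we)
                else:
                    covered = intersect_coords(ivs, [(ws, we)])
                    row[cls] = sum(e - s for s, e in covered) / (we - ws)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", *classes])
    return DensityTrack(window=window, frame=frame)
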