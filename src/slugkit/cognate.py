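"""Cognate-chromosome detection from whole-genome self-alignment.

After a whole-genome duplication each chromosome should retain a partner
("cognate") descending from the same ancestral chromosome. The statistic
used here scores, for each chromosome i and every other chromosome j,

    score(i, j) = l_ij / (L_i - M_i)

where l_ij is the number of bases of i covered by at least one alignment
block whose partner is j, L_i is the length of i and M_i its masked
(tandem + interspersed repeat) length. The j maximizing the score is the
cognate of i. Fusions and fissions leave a recognizable asymmetry: a
fused chromosome is the cognate of both ancestral partners, which are
not cognates of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intervals import merge_coords, subtract_coords
from .io import AlignmentBlock, write_tsv

log = logging.getLogger(__name__)


@dataclass
class ChromSummary:
    """Per-chromosome lengths entering the score denominator."""

    chrom: str
    length: int
    masked: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.masked <= self.length:
            raise ValueError(
                f"{self.chrom}: masked length {self.masked} outside "
                f"[0, {self.length}]"
            )

    @property
    def effective_length(self) -> int:
        return self.length - self.masked


class CoverageMatrix:
    """Sparse l[i][j]: bases of i covered by alignment to j (j != i)."""

    def __init__(self) -> None:
        self._cov: dict[str, dict[str, int]] = {}

    def get(self, i: str, j: str) -> int:
        return self._cov.get(i, {}).get(j, 0)

    def set(self, i: str, j: str, value: int) -> None:
        self._cov.setdefault(i, {})[j] = value

    def partners(self, i: str) -> dict[str, int]:
        return dict(self._cov.get(i, {}))

    def to_frame(self) -> pd.DataFrame:
        chroms = sorted(
            set(self._cov) | {j for d in self._cov.values() for j in d}
        )
        df = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
        for i, d in self._cov.items():
            for j, v in d.items():
                df.loc[i, j] = v
        return df


@dataclass
class CognateAssignment:
    chrom: str
    cognate: str
    score: float
    partner_scores: dict[str, float] = field(default_factory=dict)
    tied_partners: list[str] = field(default_factory=list)
    reciprocal: bool = False

    @property
    def second_best(self) -> tuple[str | None, float]:
        others = sorted(
            ((j, s) for j, s in self.partner_scores.items() if j != self.cognate),
            key=lambda kv: (-kv[1], kv[0]),
        )
        return others[0] if others else (None, 0.0)


def partner_coverage(
    blocks: list[AlignmentBlock],
    chroms: list[ChromSummary],
    mask: dict[str, list[tuple[int, int]]] | None = None,
    clip_to_unmasked: bool = True,
) -> CoverageMatrix:
    """Compute l[i][j] from alignment blocks.

    Both directions of a block contribute (i as query against j, and i as
    target against j); self-partner blocks (query chrom == target chrom)
    are excluded entirely. With ``clip_to_unmasked``, covered intervals
    are intersected with the unmasked complement before taking the union,
    so masked bases can never be counted as covered.
    """
    known = {c.chrom for c in chroms}
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in blocks:
        for name in (b.query_chrom, b.target_chrom):
            if name not in known:
                raise ValueError(f"alignment block names unknown chromosome {name!r}")
        if b.query_chrom == b.target_chrom:
            continue
        per_pair.setdefault((b.query_chrom, b.target_chrom), []).append(
            (b.query_start, b.query_end)
        )
        per_pair.setdefault((b.target_chrom, b.query_chrom), []).append(
            (b.target_start, b.target_end)
        )
    mask = mask or {}
    cov = CoverageMatrix()
    for (i, j), coords in per_pair.items():
        covered = merge_coords(coords)
        if clip_to_unmasked and i in mask:
            covered = subtract_coords(covered, mask[i])
        cov.set(i, j, sum(e - s for s, e in covered))
    return cov


def cognate_scores(
    cov: CoverageMatrix,
    chroms: list[ChromSummary],
    assignable: set[str] | None = None,
) -> list[CognateAssignment]:
    """Assign each chromosome its cognate.

    ``assignable`` restricts which chromosomes receive assignments of
    their own (e.g. to exclude unplaced scaffolds) while still letting
    every chromosome act as a partner. Ties on score break by larger raw
    coverage, then lexicographic id; all tied partners are reported.
    Chromosomes with zero effective length are excluded with a logged
    reason. Reciprocity is evaluated after all assignments.
    """
    summaries = {c.chrom: c for c in chroms}
    targets = sorted(assignable if assignable is not None else summaries)
    out: list[CognateAssignment] = []
    for i in targets:
        summ = summaries[i]
        if summ.effective_length <= 0:
            log.warning(
                "chromosome %s excluded: effective length is zero "
                "(L=%d, M=%d)", i, summ.length, summ.masked,
            )
            continue
        partners = {j: v for j, v in cov.partners(i).items() if j != i}
        if not partners:
            continue
        eff = summ.effective_length
        scores = {j: v / eff for j, v in partners.items()}
        best = min(
            scores, key=lambda j: (-scores[j], -partners[j], j)
        )
        tied = sorted(
            j for j in scores
            if scores[j] == scores[best] and partners[j] == partners[best]
        )
        out.append(
            CognateAssignment(
                chrom=i,
                cognate=best,
                score=scores[best],
                partner_scores=scores,
                tied_partners=tied if len(tied) > 1 else [],
            )
        )
    by_chrom = {a.chrom: a for a in out}
    for a in out:
        partner = by_chrom.get(a.cognate)
        a.reciprocal = partner is not None and partner.cognate == a.chrom
    return out


def cognate_table(
    assignments: list[CognateAssignment],
    path: str | Path | None = None,
    chroms: list[ChromSummary] | None = None,
) -> pd.DataFrame:
    """Tabulate assignments (one row per chromosome, sorted by id)."""
    eff = {c.chrom: c.effective_length for c in (chroms or [])}
    rows = []
    for a in sorted(assignments, key=lambda a: a.chrom):
        second, second_score = a.second_best
        rows.append(
            {
                "chrom": a.chrom,
                "cognate": a.cognate,
                "score": round(a.score, 6),
                "second_best": second if second is not None else ".",
                "second_score": round(second_score, 6),
                "reciprocal": a.reciprocal,
                "effective_length": eff.get(a.chrom, ""),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "cognate", "score", "second_best", "second_score",
            "reciprocal", "effective_length",
        ],
    )
    if path is not None:
        write_tsv(path, list(df.columns), df.itertuples(index=False))
    return df
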