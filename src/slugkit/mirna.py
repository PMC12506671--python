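"""Rule-based miRNA locus curation.

Candidate precursor loci are classified into four confidence categories
from expression, 5'-end definition, hairpin plausibility, overlap flags
and matching against an annotated reference set:

* ``artifact`` — repeat-derived, low-complexity, or overlapping an
  abundant piRNA locus; dominates every other signal.
* ``high`` — exact match to a reference mature miRNA, or an abundant
  main strand with a well-defined 5' end, a visible passenger strand
  and a predictable pre-miRNA-like stem loop.
* ``moderate`` — stem loop and 5' definition hold but expression is
  below the high-confidence floor (down to 20 RPM for seed-matching
  candidates, 1 RPM otherwise).
* ``ambiguous`` — everything else: very low expression, diffuse 5'
  ends, or no predictable stem loop.

Hairpin plausibility uses maximum base pairing (Nussinov dynamic
programming, pairs A-U/G-C/G-U, minimum loop 3) rather than
thermodynamic folding: it is deterministic, dependency-free, and
separates planted hairpins from non-folding precursors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

log = logging.getLogger(__name__)

_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
MATCH_CLASSES = ("exact", "seed2_10", "seed2_8", "none")
CONFIDENCE_CLASSES = ("high", "moderate", "ambiguous", "artifact")


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class ReferenceMirna:
    name: str
    family: str
    mature: str

    def __post_init__(self) -> None:
        self.mature = _normalize(self.mature)
        if len(self.mature) < 18:
            raise ValueError(f"reference {self.name}: mature shorter than 18 nt")


@dataclass
class CurationThresholds:
    high_rpm: float = 100.0
    seedmatch_rpm: float = 20.0
    min_rpm: float = 1.0
    homogeneity_min: float = 0.75
    hairpin_paired_min: float = 0.55
    hairpin_min_loop: int = 3
    # alternative reading of the moderate rule: the 20 RPM figure acts as
    # a ceiling for seed-matching candidates instead of a floor
    seed_rpm_as_ceiling: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_rpm <= self.seedmatch_rpm <= self.high_rpm:
            raise ValueError(
                "thresholds must satisfy 0 < min_rpm <= seedmatch_rpm <= high_rpm"
            )


@dataclass
class MirnaLocus:
    id: str
    precursor: str
    mature_main: str
    mature_star: str | None = None
    rpm_per_sample: list[float] = field(default_factory=list)
    five_prime_homogeneity: float = 0.0
    passenger_detected: bool = False
    repeat_overlap: bool = False
    low_complexity: bool = False
    pirna_overlap: bool = False
    match_class: str | None = None
    hairpin_passed: bool | None = None
    hairpin_paired_fraction: float | None = None
    confidence: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        self.precursor = _normalize(self.precursor)
        self.mature_main = _normalize(self.mature_main)
        if self.mature_star is not None:
            self.mature_star = _normalize(self.mature_star)
        if self.mature_main not in self.precursor:
            raise ValueError(
                f"locus {self.id}: mature_main is not a substring of the precursor"
            )
        if any(r < 0 for r in self.rpm_per_sample):
            raise ValueError(f"locus {self.id}: negative RPM")

    @property
    def max_rpm(self) -> float:
        return max(self.rpm_per_sample, default=0.0)

    @property
    def any_artifact_flag(self) -> bool:
        return self.repeat_overlap or self.low_complexity or self.pirna_overlap


def match_reference(
    mature: str, references: Sequence[ReferenceMirna]
) -> str:
    """Best reference-match class for a mature sequence.

    ``exact`` beats ``seed2_10`` (positions 2-10 identical) beats
    ``seed2_8`` (positions 2-8 identical) beats ``none``. Positions are
    1-based on the mature sequence.
    """
    mature = _normalize(mature)
    if len(mature) < 10:
        raise ValueError("mature sequence must be at least 10 nt")
    if not references:
        log.warning("empty reference set: every locus will match 'none'")
        return "none"
    best = "none"
    for ref in references:
        if mature == ref.mature:
            return "exact"
        if mature[1:10] == ref.mature[1:10]:
            best = "seed2_10" if best != "seed2_10" else best
        elif best == "none" and mature[1:8] == ref.mature[1:8]:
            best = "seed2_8"
    return best


def _nussinov(seq: str, min_loop: int) -> dict[int, int]:
    """Maximum base-pairing structure; returns the pair map i <-> j.

    Traceback prefers pairing the leftmost base with its outermost
    admissible partner, which recovers the full stem on clean hairpins
    when optima tie.
    """
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            row = dp[i + 1]
            best = row[j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in _PAIRS:
                    v = (row[k - 1] if k - 1 >= i + 1 else 0) + (
                        dp[k + 1][j] if k + 1 <= j else 0
                    ) + 1
                    if v > best:
                        best = v
            dp[i][j] = best
    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        paired = False
        for k in range(j, i + min_loop, -1):
            if (seq[i], seq[k]) in _PAIRS:
                left = dp[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = dp[k + 1][j] if k + 1 <= j else 0
                if left + right + 1 == dp[i][j]:
                    pairs[i] = k
                    pairs[k] = i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def hairpin_pass(
    precursor: str,
    mature_main: str,
    paired_min: float = 0.55,
    min_loop: int = 3,
) -> tuple[bool, float]:
    """Does the precursor fold into a pre-miRNA-like stem loop?

    The maximum base-pairing structure of the precursor is computed and
    the fraction of mature-arm positions paired to positions *outside*
    the mature arm is measured; the test passes when it reaches
    ``paired_min``. Precursors longer than 300 nt are rejected.
    """
    precursor = _normalize(precursor)
    mature_main = _normalize(mature_main)
    if len(precursor) > 300:
        raise ValueError("precursor longer than 300 nt")
    m_start = precursor.find(mature_main)
    if m_start < 0:
        raise ValueError("mature_main not found in precursor")
    m_end = m_start + len(mature_main)
    pairs = _nussinov(precursor, min_loop)
    outside = sum(
        1
        for i in range(m_start, m_end)
        if i in pairs and not (m_start <= pairs[i] < m_end)
    )
    frac = outside / len(mature_main)
    return frac >= paired_min, frac


def classify_locus(locus: MirnaLocus, thresholds: CurationThresholds) -> str:
    """Apply the four-category confidence rule.

    Precedence: artifact, then high, then moderate, then ambiguous.
    ``match_reference`` and ``hairpin_pass`` must have been evaluated
    (their results stored on the locus) before calling.
    """
    if locus.match_class is None:
        raise ValueError(f"locus {locus.id}: match_class not evaluated")
    if locus.hairpin_passed is None:
        raise ValueError(f"locus {locus.id}: hairpin_pass not evaluated")
    t = thresholds
    if locus.any_artifact_flag:
        return "artifact"
    if locus.match_class == "exact":
        return "high"
    well_defined = locus.five_prime_homogeneity >= t.homogeneity_min
    if (
        locus.max_rpm >= t.high_rpm
        and well_defined
        and locus.passenger_detected
        and locus.hairpin_passed
    ):
        return "high"
    seed_match = locus.match_class in ("seed2_10", "seed2_8")
    if t.seed_rpm_as_ceiling:
        floor = t.min_rpm
        ceiling = t.seedmatch_rpm if seed_match else t.high_rpm
    else:
        floor = t.seedmatch_rpm if seed_match else t.min_rpm
        ceiling = t.high_rpm
    if (
        locus.hairpin_passed
        and well_defined
        and floor <= locus.max_rpm < ceiling
    ):
        return "moderate"
    return "ambiguous"


def assign_family(
    mature: str, references: Sequence[ReferenceMirna]
) -> tuple[str | None, str]:
    """Family of the best reference hit, with the match level.

    Returns ``(family, level)`` where level is exact/seed2_10/seed2_8,
    or ``(None, "none")`` when nothing matches.
    """
    mature = _normalize(mature)
    best: tuple[str | None, str] = (None, "none")
    order = {c: i for i, c in enumerate(MATCH_CLASSES)}
    for ref in references:
        if mature == ref.mature:
            level = "exact"
        elif mature[1:10] == ref.mature[1:10]:
            level = "seed2_10"
        elif mature[1:8] == ref.mature[1:8]:
            level = "seed2_8"
        else:
            continue
        if order[level] < order[best[1]]:
            best = (ref.family, level)
    return best


def curate(
    loci: Sequence[MirnaLocus],
    references: Sequence[ReferenceMirna],
    thresholds: CurationThresholds | None = None,
) -> list[MirnaLocus]:
    """Run the full curation pipeline over a locus list, in place."""
    t = thresholds or CurationThresholds()
    for locus in loci:
        locus.match_class = match_reference(locus.mature_main, references)
        locus.hairpin_passed, locus.hairpin_paired_fraction = hairpin_pass(
            locus.precursor,
            locus.mature_main,
            paired_min=t.hairpin_paired_min,
            min_loop=t.hairpin_min_loop,
        )
        locus.confidence = classify_locus(locus, t)
        locus.family, _ = assign_family(locus.mature_main, references)
    return list(loci)
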