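"""Paralog linking by jaccard similarity of ortholog sets.

Two genes that share most of their assigned orthologs are putative
paralogs (within one genome, often ohnologs from whole-genome
duplication). A link is drawn when the jaccard similarity of the two
ortholog sets exceeds a threshold; links are classified by genomic
relationship and chained into positional clusters of related genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Sequence

import pandas as pd

DEFAULT_WINDOW = 5_000_000  # bp separating "near" from "far" intra-chrom pairs
DEFAULT_MIN_SIZE = 5


@dataclass(frozen=True)
class GeneEntry:
    id: str
    chrom: str
    start: int
    end: int
    ortholog_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class ParalogEdge:
    gene_a: str
    gene_b: str
    jaccard: float
    relation: str  # interchromosomal | intra_far | intra_near


@dataclass
class GeneCluster:
    chrom: str
    members: list[str]
    start: int
    end: int
    label: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start


def jaccard_similarity(set_a: AbstractSet, set_b: AbstractSet) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


def _relation(a: GeneEntry, b: GeneEntry, window: int) -> str:
    if a.chrom != b.chrom:
        return "interchromosomal"
    if abs(a.midpoint - b.midpoint) > window:
        return "intra_far"
    return "intra_near"


def build_paralog_links(
    genes: Sequence[GeneEntry],
    threshold: float = 0.5,
    window: int = DEFAULT_WINDOW,
) -> list[ParalogEdge]:
    """Link all unordered gene pairs with jaccard > threshold (strict).

    Distance between genes is measured between interval midpoints.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    # bucket genes by ortholog member so only pairs sharing >= 1 ortholog
    # are examined; disjoint sets can never clear a positive threshold
    by_member: dict[str, list[int]] = {}
    for idx, g in enumerate(genes):
        for m in g.ortholog_set:
            by_member.setdefault(m, []).append(idx)
    candidate: set[tuple[int, int]] = set()
    for idxs in by_member.values():
        for i_pos, i in enumerate(idxs):
            for j in idxs[i_pos + 1:]:
                candidate.add((i, j))
    edges = []
    for i, j in candidate:
        a, b = genes[i], genes[j]
        jac = jaccard_similarity(a.ortholog_set, b.ortholog_set)
        if jac > threshold:
            ga, gb = sorted((a, b), key=lambda g: g.id)
            edges.append(
                ParalogEdge(ga.id, gb.id, jac, _relation(ga, gb, window))
            )
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def detect_gene_clusters(
    genes: Sequence[GeneEntry],
    edges: Sequence[ParalogEdge],
    min_size: int = DEFAULT_MIN_SIZE,
    window: int = DEFAULT_WINDOW,
) -> list[GeneCluster]:
    """Positional clusters of linked genes.

    Within each chromosome, connected components of the link graph are
    chained by position: a run extends while the next member gene starts
    within ``window`` of the previous one and the total span (max end -
    min start) stays <= window. Runs with >= min_size members are
    reported, sorted by (chrom, start).
    """
    by_id = {g.id: g for g in genes}
    # union-find over gene ids appearing in edges
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        for gid in (e.gene_a, e.gene_b):
            parent.setdefault(gid, gid)
        ra, rb = find(e.gene_a), find(e.gene_b)
        if ra != rb:
            parent[ra] = rb
    components: dict[str, list[GeneEntry]] = {}
    for gid in parent:
        components.setdefault(find(gid), []).append(by_id[gid])
    clusters: list[GeneCluster] = []
    for comp in components.values():
        per_chrom: dict[str, list[GeneEntry]] = {}
        for g in comp:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, members in per_chrom.items():
            members.sort(key=lambda g: (g.start, g.id))
            run: list[GeneEntry] = []
            for g in members:
                if run and (
                    g.start - run[-1].start > window
                    or max(g.end, max(m.end for m in run)) - run[0].start > window
                ):
                    if len(run) >= min_size:
                        clusters.append(_make_cluster(chrom, run))
                    run = []
                run.append(g)
            if len(run) >= min_size:
                clusters.append(_make_cluster(chrom, run))
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def _make_cluster(chrom: str, members: list[GeneEntry]) -> GeneCluster:
    return GeneCluster(
        chrom=chrom,
        members=[g.id for g in members],
        start=min(g.start for g in members),
        end=max(g.end for g in members),
    )


def chromosome_connection_counts(
    edges: Sequence[ParalogEdge], genes: Sequence[GeneEntry]
) -> pd.DataFrame:
    """Symmetric matrix of link counts per chromosome pair.

    The diagonal holds intra-chromosomal link counts.
    """
    chrom_of = {g.id: g.chrom for g in genes}
    chroms = sorted({g.chrom for g in genes})
    df = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    for e in edges:
        ca, cb = chrom_of[e.gene_a], chrom_of[e.gene_b]
        df.loc[ca, cb] += 1
        if ca != cb:
            df.loc[cb, ca] += 1
    return df


def segmental_duplication_pairs(
    edges: Sequence[ParalogEdge],
) -> list[ParalogEdge]:
    """Proximal intra-chromosomal paralog pairs (putative segmental
    duplications): the ``intra_near`` edges."""
    return [e for e in edges if e.relation == "intra_near"]
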