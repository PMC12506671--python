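"""Synthetic data with planted ground truth for every pipeline stage.

Each generator is a pure function of its configuration (seed included):
identical configuration gives byte-identical output. The generators
emulate the data-generating conditions of a post-WGD gastropod genome
study at desk scale — a duplicated genome with fusions/fissions and
repeat masking, small-RNA read populations with configurable 1U bias
and ping-pong pairing, ortholog-set tables with planted paralog
clusters, and GFF3 annotations with known summary statistics — so every
analysis stage can be tested against known truth without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np

from .annotation import AnnotationStats, GeneModel, Transcript
from .intervals import GenomicInterval, merge_coords
from .io import AlignmentBlock, SeqRecord
from .mirna import MirnaLocus, ReferenceMirna
from .paralogs import GeneEntry
from .smallrna import AlignedRead

_BASES = np.array(list("ACGT"))
_RNA = "ACGU"
# per-section stream tags so the five generators draw independent streams
_TAG_WGD, _TAG_SRNA, _TAG_MIRNA, _TAG_ORTHO, _TAG_ANNOT = range(5)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class WgdConfig:
    n_ancestral_chroms: int = 3
    chrom_length: int = 200_000
    divergence: float = 0.05
    n_fusions: int = 0
    n_fissions: int = 0
    masked_fraction: float = 0.10
    telomere_copies: int = 50       # TTAGGG copies inserted at fusion junctions
    block_size: int = 50_000        # max alignment-block size
    boundary_jitter: float = 0.05   # relative jitter on block boundaries
    mask_segment: int = 2_000       # length of each placed mask interval

    def validate(self) -> None:
        if self.n_ancestral_chroms < 2:
            raise ValueError("need at least 2 ancestral chromosomes")
        if not 0 <= self.divergence < 0.3:
            raise ValueError("divergence must be in [0, 0.3)")
        if not 0 <= self.masked_fraction < 1:
            raise ValueError("masked_fraction must be in [0, 1)")
        if self.n_fusions * 2 + self.n_fissions > self.n_ancestral_chroms:
            raise ValueError(
                f"{self.n_fusions} fusions and {self.n_fissions} fissions "
                f"exceed the {self.n_ancestral_chroms} available chromosome pairs"
            )


@dataclass
class SmallRnaConfig:
    n_reads: int = 20_000
    length_mean: float = 29.0
    length_sd: float = 1.0
    length_range: tuple[int, int] = (18, 32)
    u1_prob: float = 0.8
    # 1U bias of background reads; None means "same as u1_prob". Setting it
    # lower plants the cluster-restricted 1U enrichment seen in real piRNA data.
    background_u1_prob: float | None = None
    a10_prob_secondary: float = 0.7
    pingpong_fraction: float = 0.2
    n_clusters: int = 20
    cluster_length: int = 5_000
    background_read_fraction: float = 0.05
    n_chroms: int = 4
    chrom_length: int = 1_000_000

    def validate(self) -> None:
        for name in ("u1_prob", "a10_prob_secondary", "pingpong_fraction",
                     "background_read_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_u1_prob is not None and not 0 <= self.background_u1_prob <= 1:
            raise ValueError("background_u1_prob must be in [0, 1]")
        if self.pingpong_fraction + self.background_read_fraction > 1:
            raise ValueError(
                "pingpong_fraction + background_read_fraction must be <= 1"
            )
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_length > self.chrom_length:
            raise ValueError("cluster longer than its chromosome")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError("bad length_range")


@dataclass
class MirnaSimConfig:
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "high": 25, "moderate": 25, "ambiguous": 25, "artifact": 25
        }
    )
    n_references: int = 50
    mature_length: int = 22
    loop_length: int = 8
    flank_length: int = 5
    high_rpm_range: tuple[float, float] = (150.0, 1000.0)
    moderate_seed_rpm_range: tuple[float, float] = (25.0, 90.0)
    moderate_rpm_range: tuple[float, float] = (2.0, 90.0)
    low_rpm_range: tuple[float, float] = (0.05, 0.8)
    high_homogeneity_range: tuple[float, float] = (0.85, 1.0)
    diffuse_homogeneity_range: tuple[float, float] = (0.2, 0.6)

    def validate(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        bad = set(self.class_counts) - {"high", "moderate", "ambiguous", "artifact"}
        if bad:
            raise ValueError(f"unknown miRNA classes {sorted(bad)}")


@dataclass
class OrthologConfig:
    n_genes: int = 400
    n_chroms: int = 6
    chrom_length: int = 40_000_000
    n_planted_clusters: int = 4
    cluster_size: int = 5
    cluster_span: int = 2_000_000
    planted_pair_fraction: float = 0.3
    gene_length: int = 5_000

    def validate(self) -> None:
        if self.cluster_size < 5:
            raise ValueError("cluster_size must be >= 5")
        if self.n_genes < 2 * self.cluster_size * self.n_planted_clusters:
            raise ValueError(
                "n_genes must be >= 2 * cluster_size * n_planted_clusters"
            )
        if self.n_chroms % 2 or self.n_chroms < 2:
            raise ValueError("n_chroms must be a positive even number")
        if self.cluster_span > self.chrom_length:
            raise ValueError("cluster span exceeds chromosome length")


@dataclass
class AnnotationSimConfig:
    n_genes: int = 120
    chrom: str = "an1"
    isoform_prob: float = 0.2
    monoexonic_fraction: float = 0.15
    mean_exons_per_multiexonic: float = 8.0
    exon_length_mean: float = 250.0
    exon_length_sigma: float = 0.5
    intron_length_mean: float = 1_500.0
    intron_length_sigma: float = 0.7
    utr_complete_fraction: float = 0.45
    intergenic_mean: float = 3_000.0

    def validate(self) -> None:
        for name in ("isoform_prob", "monoexonic_fraction", "utr_complete_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_exons_per_multiexonic < 2:
            raise ValueError("mean_exons_per_multiexonic must be >= 2")


@dataclass
class SimConfig:
    seed: int = 0
    wgd: WgdConfig = field(default_factory=WgdConfig)
    smallrna: SmallRnaConfig = field(default_factory=SmallRnaConfig)
    mirna: MirnaSimConfig = field(default_factory=MirnaSimConfig)
    orthologs: OrthologConfig = field(default_factory=OrthologConfig)
    annotation: AnnotationSimConfig = field(default_factory=AnnotationSimConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        sections = {
            "wgd": WgdConfig, "smallrna": SmallRnaConfig, "mirna": MirnaSimConfig,
            "orthologs": OrthologConfig, "annotation": AnnotationSimConfig,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections {sorted(unknown)}")
        kwargs: dict[str, Any] = {"seed": int(data.get("seed", 0))}
        for name, klass in sections.items():
            section = dict(data.get(name, {}))
            valid = {f.name for f in fields(klass)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            for key in ("length_range",):  # tuples arrive as lists from YAML/TOML
                if key in section:
                    section[key] = tuple(section[key])
            kwargs[name] = klass(**section)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"config must be .yaml/.yml/.toml, got {path.suffix}")
        return cls.from_dict(data)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# ---------------------------------------------------------------------------
# WGD genome

@dataclass
class WgdTruth:
    cognate_map: dict[str, tuple[str, ...]]
    chrom_lengths: dict[str, int]
    junctions: list[GenomicInterval]
    fused_chroms: list[str]
    fission_pieces: list[tuple[str, str]]


@dataclass
class WgdSimulation:
    genome: list[SeqRecord]
    mask: dict[str, list[tuple[int, int]]]
    blocks: list[AlignmentBlock]
    truth: WgdTruth

    def chrom_lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.genome}


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if divergence > 0:
        hit = rng.random(seq.size) < divergence
        out[hit] = (out[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def simulate_wgd_genome(config: SimConfig) -> WgdSimulation:
    """A duplicated genome with optional fusions/fissions.

    Every ancestral chromosome is emitted twice, each copy mutated
    independently at the per-base divergence rate. A fusion joins the
    second copies of two different ancestors into one chromosome with a
    TTAGGG tandem array at the junction (so the fused chromosome is the
    WGD partner of two others); a fission splits a second copy in two.
    Alignment blocks come straight from the known homology map — no
    aligner runs — cut into <= block_size pieces with jittered
    boundaries, each piece dropped with probability equal to the
    divergence. Mask intervals cover masked_fraction of each chromosome
    uniformly; fusion-junction arrays are masked as tandem repeats.
    """
    cfg = config.wgd
    cfg.validate()
    rng = _rng(config.seed, _TAG_WGD)
    n = cfg.n_ancestral_chroms
    L = cfg.chrom_length
    ancestral = [rng.integers(0, 4, L) for _ in range(n)]
    copies = {}  # (ancestor, copy) -> mutated array
    for a in range(n):
        for c in (1, 2):
            copies[(a, c)] = _mutate(ancestral[a], cfg.divergence, rng)

    telomere = np.array(
        [_BASES.tolist().index(b) for b in "TTAGGG" * cfg.telomere_copies]
    )

    # layout: each final chromosome is a list of (ancestor, copy, src_start,
    # src_end, offset); fusion inserts a telomeric array between two units
    chrom_segments: dict[str, list[tuple[int, int, int, int, int]]] = {}
    sequences: dict[str, np.ndarray] = {}
    junctions: list[GenomicInterval] = []
    fused_chroms: list[str] = []
    fission_pieces: list[tuple[str, str]] = []
    names: dict[tuple[int, int], list[str]] = {}  # unit -> final chrom name(s)
    counter = [0]

    def next_name() -> str:
        counter[0] += 1
        return f"chr{counter[0]}"

    # first copies are always whole chromosomes
    for a in range(n):
        name = next_name()
        names[(a, 1)] = [name]
        chrom_segments[name] = [(a, 1, 0, L, 0)]
        sequences[name] = copies[(a, 1)]
    # second copies: fused in consecutive ancestor pairs, then fissioned,
    # then plain
    fusion_members = [(2 * k, 2 * k + 1) for k in range(cfg.n_fusions)]
    fission_set = set(
        range(2 * cfg.n_fusions, 2 * cfg.n_fusions + cfg.n_fissions)
    )
    fused_ancestors = {a for pair in fusion_members for a in pair}
    for a, b in fusion_members:
        name = next_name()
        fused_chroms.append(name)
        names[(a, 2)] = [name]
        names[(b, 2)] = [name]
        seq = np.concatenate([copies[(a, 2)], telomere, copies[(b, 2)]])
        sequences[name] = seq
        offset_b = L + telomere.size
        chrom_segments[name] = [
            (a, 2, 0, L, 0),
            (b, 2, 0, L, offset_b),
        ]
        junctions.append(GenomicInterval(name, L, L + telomere.size))
    for a in range(n):
        if a in fused_ancestors:
            continue
        if a in fission_set:
            cut = L // 2
            n1, n2 = next_name(), next_name()
            names[(a, 2)] = [n1, n2]
            sequences[n1] = copies[(a, 2)][:cut]
            sequences[n2] = copies[(a, 2)][cut:]
            chrom_segments[n1] = [(a, 2, 0, cut, 0)]
            chrom_segments[n2] = [(a, 2, cut, L, 0)]
            fission_pieces.append((n1, n2))
        else:
            name = next_name()
            names[(a, 2)] = [name]
            sequences[name] = copies[(a, 2)]
            chrom_segments[name] = [(a, 2, 0, L, 0)]

    # truth cognate map: copy 1 of each ancestor <-> wherever copy 2 went
    cognate_map: dict[str, set[str]] = {c: set() for c in sequences}
    for a in range(n):
        for c1 in names[(a, 1)]:
            for c2 in names[(a, 2)]:
                cognate_map[c1].add(c2)
                cognate_map[c2].add(c1)

    # alignment blocks from the homology map
    blocks: list[AlignmentBlock] = []
    seg_index: dict[tuple[int, int], list[tuple[int, int, str, int]]] = {}
    for name, segs in chrom_segments.items():
        for a, c, s, e, off in segs:
            seg_index.setdefault((a, c), []).append((s, e, name, off))
    for segs in seg_index.values():
        segs.sort()

    def locate(a: int, c: int, pos: int) -> tuple[str, int]:
        for s, e, name, off in seg_index[(a, c)]:
            if s <= pos < e:
                return name, off + (pos - s)
        raise AssertionError("position outside all segments")

    for a in range(n):
        # cut points: jittered block grid plus any fission boundary
        cuts = {0, L}
        pos = 0
        while pos < L:
            step = int(
                cfg.block_size
                * (1 + rng.uniform(-cfg.boundary_jitter, cfg.boundary_jitter))
            )
            pos = min(L, pos + max(1, step))
            cuts.add(pos)
        for s, e, _, _ in seg_index[(a, 2)]:
            cuts.update((s, e))
        bounds = sorted(cuts)
        for s, e in zip(bounds, bounds[1:]):
            if rng.random() < cfg.divergence:
                continue  # dropout stands in for alignment failure
            q_chrom, q_off = locate(a, 1, s)
            t_chrom, t_off = locate(a, 2, s)
            blocks.append(
                AlignmentBlock(
                    q_chrom, q_off, q_off + (e - s),
                    t_chrom, t_off, t_off + (e - s),
                    "+", float(e - s),
                )
            )

    # masks: aligned non-overlapping segments covering masked_fraction
    mask: dict[str, list[tuple[int, int]]] = {c: [] for c in sequences}
    for name in sorted(sequences):
        clen = sequences[name].size
        n_slots = clen // cfg.mask_segment
        n_pick = int(round(cfg.masked_fraction * clen / cfg.mask_segment))
        if n_pick > 0 and n_slots > 0:
            slots = rng.choice(n_slots, size=min(n_pick, n_slots), replace=False)
            mask[name] = [
                (int(s) * cfg.mask_segment, (int(s) + 1) * cfg.mask_segment)
                for s in sorted(slots)
            ]
    for j in junctions:
        mask[j.chrom] = merge_coords(mask[j.chrom] + [(j.start, j.end)])

    genome = [
        SeqRecord(name, "".join(_BASES[sequences[name]]))
        for name in sorted(sequences, key=lambda s: int(s[3:]))
    ]
    truth = WgdTruth(
        cognate_map={c: tuple(sorted(v)) for c, v in cognate_map.items()},
        chrom_lengths={r.id: len(r) for r in genome},
        junctions=junctions,
        fused_chroms=fused_chroms,
        fission_pieces=fission_pieces,
    )
    return WgdSimulation(genome=genome, mask=mask, blocks=blocks, truth=truth)


# ---------------------------------------------------------------------------
# small-RNA reads

@dataclass
class SmallRnaTruth:
    clusters: list[tuple[GenomicInterval, str]]
    n_primary: int
    n_secondary: int
    n_background: int
    chrom_lengths: dict[str, int]
    config: SmallRnaConfig


@dataclass
class SmallRnaSimulation:
    reads: list[AlignedRead]
    truth: SmallRnaTruth


def _draw_length(cfg: SmallRnaConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.length_range
    return int(np.clip(round(rng.normal(cfg.length_mean, cfg.length_sd)), lo, hi))


def _random_seq(n: int, rng: np.random.Generator) -> list[str]:
    return [_RNA[i] for i in rng.integers(0, 4, n)]


def simulate_smallrna_reads(config: SimConfig) -> SmallRnaSimulation:
    """Small-RNA reads with planted clusters and ping-pong pairs.

    Primary reads fall inside cluster intervals on the cluster's
    orientation with first nucleotide U at probability u1_prob. A
    pingpong_fraction of reads are secondary partners of sampled
    primaries: opposite strand, 5' ends overlapping the partner's by
    exactly 10 nt, position-10 nucleotide A at probability
    a10_prob_secondary. Background reads land uniformly genome-wide.

    Placement guarantees that exact-10 opposite-strand overlaps happen
    only between planted partner pairs: 5' positions are unique per
    (chromosome, strand), and background reads are rejected from any
    position that would create a coincidental exact-10 pair.
    """
    cfg = config.smallrna
    cfg.validate()
    rng = _rng(config.seed, _TAG_SRNA)
    chroms = [f"sr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: cfg.chrom_length for c in chroms}

    clusters: list[tuple[GenomicInterval, str]] = []
    margin = 200
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(cfg.n_clusters):
        for _attempt in range(1000):
            chrom = chroms[rng.integers(0, cfg.n_chroms)]
            start = int(rng.integers(0, cfg.chrom_length - cfg.cluster_length))
            iv = (start - margin, start + cfg.cluster_length + margin)
            if all(e <= iv[0] or s >= iv[1] for s, e in placed[chrom]):
                placed[chrom].append(iv)
                orientation = "+" if rng.random() < 0.5 else "-"
                clusters.append(
                    (GenomicInterval(chrom, start, start + cfg.cluster_length),
                     orientation)
                )
                break
        else:
            raise ValueError("could not place non-overlapping clusters")

    n_secondary = int(round(cfg.n_reads * cfg.pingpong_fraction))
    n_background = int(round(cfg.n_reads * cfg.background_read_fraction))
    n_primary = cfg.n_reads - n_secondary - n_background

    plus_starts: dict[str, set[int]] = {c: set() for c in chroms}
    minus_ends: dict[str, set[int]] = {c: set() for c in chroms}
    reads: list[AlignedRead] = []
    primaries: list[AlignedRead] = []

    def five_prime_free(chrom: str, strand: str, start: int, end: int) -> bool:
        if strand == "+":
            return start not in plus_starts[chrom]
        return end not in minus_ends[chrom]

    def register(chrom: str, strand: str, start: int, end: int) -> None:
        if strand == "+":
            plus_starts[chrom].add(start)
        else:
            minus_ends[chrom].add(end)

    def primary_seq(length: int, u1: float) -> str:
        seq = _random_seq(length, rng)
        if rng.random() < u1:
            seq[0] = "U"
        else:
            seq[0] = "ACG"[rng.integers(0, 3)]
        return "".join(seq)

    bg_u1 = cfg.u1_prob if cfg.background_u1_prob is None else cfg.background_u1_prob

    for _ in range(n_primary):
        for _attempt in range(1000):
            iv, orientation = clusters[rng.integers(0, len(clusters))]
            length = _draw_length(cfg, rng)
            start = iv.start + int(rng.integers(0, iv.length - length))
            end = start + length
            if five_prime_free(iv.chrom, orientation, start, end):
                register(iv.chrom, orientation, start, end)
                read = AlignedRead(
                    iv.chrom, start, end, orientation,
                    primary_seq(length, cfg.u1_prob),
                )
                reads.append(read)
                primaries.append(read)
                break
        else:
            raise ValueError("could not place primary reads with unique 5' ends")

    for _ in range(n_secondary):
        for _attempt in range(1000):
            p = primaries[rng.integers(0, len(primaries))]
            length = _draw_length(cfg, rng)
            if p.strand == "+":
                strand, end = "-", p.start + 10
                start = end - length
            else:
                strand, start = "+", p.end - 10
                end = start + length
            if start < 0 or end > chrom_lengths[p.chrom]:
                continue
            if five_prime_free(p.chrom, strand, start, end):
                register(p.chrom, strand, start, end)
                seq = _random_seq(length, rng)
                if rng.random() < cfg.a10_prob_secondary:
                    seq[9] = "A"
                else:
                    seq[9] = "CGU"[rng.integers(0, 3)]
                reads.append(AlignedRead(p.chrom, start, end, strand, "".join(seq)))
                break
        else:
            raise ValueError("could not place secondary reads")

    for _ in range(n_background):
        for _attempt in range(1000):
            chrom = chroms[rng.integers(0, cfg.n_chroms)]
            strand = "+" if rng.random() < 0.5 else "-"
            length = _draw_length(cfg, rng)
            start = int(rng.integers(0, cfg.chrom_length - length))
            end = start + length
            if not five_prime_free(chrom, strand, start, end):
                continue
            # forbid coincidental exact-10 overlaps with any placed read
            if strand == "+" and (start + 10) in minus_ends[chrom]:
                continue
            if strand == "-" and (end - 10) in plus_starts[chrom]:
                continue
            register(chrom, strand, start, end)
            reads.append(
                AlignedRead(chrom, start, end, strand, primary_seq(length, bg_u1))
            )
            break
        else:
            raise ValueError("could not place background reads")

    truth = SmallRnaTruth(
        clusters=clusters,
        n_primary=n_primary,
        n_secondary=n_secondary,
        n_background=n_background,
        chrom_lengths=chrom_lengths,
        config=cfg,
    )
    return SmallRnaSimulation(reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# miRNA loci

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class MirnaSimulation:
    loci: list[MirnaLocus]
    references: list[ReferenceMirna]
    truth: dict[str, str]  # locus id -> intended confidence class


def _rand_rna(n: int, rng: np.random.Generator) -> str:
    return "".join(_RNA[i] for i in rng.integers(0, 4, n))


def _hairpin_precursor(
    mature: str, cfg: MirnaSimConfig, rng: np.random.Generator, n_mismatch: int
) -> tuple[str, str]:
    """Precursor with the mature arm base-paired into the star arm,
    carrying up to n_mismatch broken pairs. Returns (precursor, star)."""
    star = [_RNA_COMP[c] for c in reversed(mature)]
    if n_mismatch:
        pos = rng.choice(len(star), size=n_mismatch, replace=False)
        for j in pos:
            partner = mature[len(mature) - 1 - j]
            choices = [b for b in _RNA if (partner, b) not in _RNA_PAIRS]
            star[j] = choices[rng.integers(0, len(choices))]
    star_s = "".join(star)
    precursor = (
        _rand_rna(cfg.flank_length, rng)
        + mature
        + _rand_rna(cfg.loop_length, rng)
        + star_s
        + _rand_rna(cfg.flank_length, rng)
    )
    return precursor, star_s


def _rpm_samples(max_rpm: float, rng: np.random.Generator) -> list[float]:
    return [
        float(max_rpm * rng.uniform(0.2, 0.9)),
        float(max_rpm * rng.uniform(0.2, 0.9)),
        float(max_rpm),
    ]


def simulate_mirna_loci(config: SimConfig) -> MirnaSimulation:
    """Candidate miRNA loci planted per target confidence class.

    High-confidence loci get either a mature copied verbatim from the
    reference set or abundant expression with a clean hairpin;
    moderate-confidence loci sit below the high-RPM floor (some matching
    reference seeds); ambiguous loci have very low expression, diffuse
    5' ends or scrambled non-pairing precursors; artifact loci carry
    repeat/low-complexity/piRNA overlap flags.
    """
    cfg = config.mirna
    cfg.validate()
    rng = _rng(config.seed, _TAG_MIRNA)
    references = [
        ReferenceMirna(
            name=f"ref-{i + 1}",
            family=f"fam-{i // 2 + 1}",
            mature=_rand_rna(cfg.mature_length, rng),
        )
        for i in range(cfg.n_references)
    ]
    ref_matures = {r.mature for r in references}

    from .mirna import match_reference  # local to avoid cycle at import time

    def fresh_mature() -> str:
        while True:
            m = _rand_rna(cfg.mature_length, rng)
            if match_reference(m, references) == "none":
                return m

    loci: list[MirnaLocus] = []
    truth: dict[str, str] = {}
    counter = 0

    def add(locus: MirnaLocus, klass: str) -> None:
        loci.append(locus)
        truth[locus.id] = klass

    for i in range(cfg.class_counts.get("high", 0)):
        counter += 1
        if i % 2 == 0:
            mature = references[int(rng.integers(0, len(references)))].mature
        else:
            mature = fresh_mature()
        precursor, star = _hairpin_precursor(
            mature, cfg, rng, int(rng.integers(0, 3))
        )
        add(
            MirnaLocus(
                id=f"mir-{counter:04d}",
                precursor=precursor,
                mature_main=mature,
                mature_star=star,
                rpm_per_sample=_rpm_samples(rng.uniform(*cfg.high_rpm_range), rng),
                five_prime_homogeneity=float(
                    rng.uniform(*cfg.high_homogeneity_range)
                ),
                passenger_detected=True,
            ),
            "high",
        )

    for i in range(cfg.class_counts.get("moderate", 0)):
        counter += 1
        if i % 2 == 0:  # seed-matching candidate
            ref = references[int(rng.integers(0, len(references)))]
            mature = list(fresh_mature())
            mature[1:10] = ref.mature[1:10]
            # keep position 1 different so the match stays seed-level
            choices = [b for b in _RNA if b != ref.mature[0]]
            mature[0] = choices[int(rng.integers(0, 3))]
            mature_s = "".join(mature)
            if mature_s in ref_matures:  # vanishing chance; resample base
                mature_s = fresh_mature()
                rpm = rng.uniform(*cfg.moderate_rpm_range)
            else:
                rpm = rng.uniform(*cfg.moderate_seed_rpm_range)
            mature = mature_s
        else:
            mature = fresh_mature()
            rpm = rng.uniform(*cfg.moderate_rpm_range)
        precursor, star = _hairpin_precursor(mature, cfg, rng, int(rng.integers(0, 3)))
        add(
            MirnaLocus(
                id=f"mir-{counter:04d}",
                precursor=precursor,
                mature_main=mature,
                mature_star=star,
                rpm_per_sample=_rpm_samples(float(rpm), rng),
                five_prime_homogeneity=float(
                    rng.uniform(*cfg.high_homogeneity_range)
                ),
                passenger_detected=False,
            ),
            "moderate",
        )

    for i in range(cfg.class_counts.get("ambiguous", 0)):
        counter += 1
        mature = fresh_mature()
        subtype = i % 3
        homogeneity = float(rng.uniform(*cfg.high_homogeneity_range))
        rpm = float(rng.uniform(*cfg.low_rpm_range))
        if subtype == 1:
            # scrambled precursor: the non-mature part is shuffled so no
            # planted star arm exists
            precursor, _ = _hairpin_precursor(mature, cfg, rng, 0)
            rest = np.array(list(precursor[cfg.flank_length + cfg.mature_length:]))
            rng.shuffle(rest)
            precursor = (
                precursor[: cfg.flank_length]
                + mature
                + "".join(rest)
            )
            star = None
        else:
            precursor, star = _hairpin_precursor(mature, cfg, rng, 0)
            if subtype == 2:  # diffuse 5' end, ordinary expression
                homogeneity = float(rng.uniform(*cfg.diffuse_homogeneity_range))
                rpm = float(rng.uniform(*cfg.moderate_rpm_range))
        add(
            MirnaLocus(
                id=f"mir-{counter:04d}",
                precursor=precursor,
                mature_main=mature,
                mature_star=star,
                rpm_per_sample=_rpm_samples(rpm, rng),
                five_prime_homogeneity=homogeneity,
                passenger_detected=False,
            ),
            "ambiguous",
        )

    flag_cycle = (
        {"repeat_overlap": True},
        {"low_complexity": True},
        {"pirna_overlap": True},
        {"repeat_overlap": True, "low_complexity": True, "pirna_overlap": True},
    )
    for i in range(cfg.class_counts.get("artifact", 0)):
        counter += 1
        if i % 2 == 0:
            mature = references[int(rng.integers(0, len(references)))].mature
        else:
            mature = fresh_mature()
        precursor, star = _hairpin_precursor(mature, cfg, rng, 0)
        add(
            MirnaLocus(
                id=f"mir-{counter:04d}",
                precursor=precursor,
                mature_main=mature,
                mature_star=star,
                rpm_per_sample=_rpm_samples(float(rng.uniform(1, 500)), rng),
                five_prime_homogeneity=float(rng.uniform(0.5, 1.0)),
                passenger_detected=bool(rng.random() < 0.5),
                **flag_cycle[i % 4],
            ),
            "artifact",
        )

    return MirnaSimulation(loci=loci, references=references, truth=truth)


# ---------------------------------------------------------------------------
# ortholog tables

@dataclass
class OrthologTruth:
    edges: set[tuple[str, str]]
    clusters: list[list[str]]
    wgd_pairs: list[tuple[str, str]]
    cognate_chrom_pairs: list[tuple[str, str]]


@dataclass
class OrthologSimulation:
    genes: list[GeneEntry]
    truth: OrthologTruth


def simulate_ortholog_table(config: SimConfig) -> OrthologSimulation:
    """Gene positions and ortholog sets with planted paralogy structure.

    Planted clusters share identical ortholog sets within a <= 5 Mb span
    on one chromosome; planted WGD pairs sit at similar positions on
    cognate chromosome pairs with high-jaccard sets; all remaining genes
    get disjoint singleton-style sets (pairwise jaccard 0).
    """
    cfg = config.orthologs
    cfg.validate()
    rng = _rng(config.seed, _TAG_ORTHO)
    chroms = [f"oc{i + 1}" for i in range(cfg.n_chroms)]
    cognate_pairs = [
        (chroms[2 * k], chroms[2 * k + 1]) for k in range(cfg.n_chroms // 2)
    ]
    og_counter = [0]

    def new_ogs(n: int) -> frozenset[str]:
        out = frozenset(
            f"OG{og_counter[0] + i + 1:06d}" for i in range(n)
        )
        og_counter[0] += n
        return out

    genes: list[GeneEntry] = []
    gid = [0]

    def add_gene(chrom: str, start: int, ogs: frozenset[str]) -> GeneEntry:
        gid[0] += 1
        g = GeneEntry(
            id=f"g{gid[0]:05d}", chrom=chrom, start=start,
            end=start + cfg.gene_length, ortholog_set=ogs,
        )
        genes.append(g)
        return g

    clusters: list[list[str]] = []
    for k in range(cfg.n_planted_clusters):
        chrom = chroms[k % cfg.n_chroms]
        base = int(
            rng.integers(0, cfg.chrom_length - cfg.cluster_span - cfg.gene_length)
        )
        ogs = new_ogs(4)
        step = cfg.cluster_span // cfg.cluster_size
        members = [
            add_gene(chrom, base + j * step, ogs).id
            for j in range(cfg.cluster_size)
        ]
        clusters.append(members)

    n_cluster_genes = cfg.n_planted_clusters * cfg.cluster_size
    n_pairs = int(round(cfg.planted_pair_fraction * cfg.n_genes / 2))
    n_pairs = min(n_pairs, (cfg.n_genes - n_cluster_genes) // 2)
    wgd_pairs: list[tuple[str, str]] = []
    for k in range(n_pairs):
        ca, cb = cognate_pairs[int(rng.integers(0, len(cognate_pairs)))]
        pos = int(rng.integers(0, cfg.chrom_length - cfg.gene_length))
        jitter = int(rng.integers(-50_000, 50_000))
        pos_b = int(np.clip(pos + jitter, 0, cfg.chrom_length - cfg.gene_length))
        if k % 2 == 0:
            ogs_a = ogs_b = new_ogs(4)  # jaccard 1
        else:
            shared = new_ogs(3)
            ogs_a = shared | new_ogs(1)
            ogs_b = shared | new_ogs(1)  # jaccard 3/5 = 0.6
        a = add_gene(ca, pos, frozenset(ogs_a))
        b = add_gene(cb, pos_b, frozenset(ogs_b))
        wgd_pairs.append((a.id, b.id))

    while len(genes) < cfg.n_genes:
        chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
        pos = int(rng.integers(0, cfg.chrom_length - cfg.gene_length))
        add_gene(chrom, pos, new_ogs(3))

    edges: set[tuple[str, str]] = set()
    for members in clusters:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                edges.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
    for a, b in wgd_pairs:
        edges.add(tuple(sorted((a, b))))  # type: ignore[arg-type]

    truth = OrthologTruth(
        edges=edges,
        clusters=clusters,
        wgd_pairs=wgd_pairs,
        cognate_chrom_pairs=cognate_pairs,
    )
    return OrthologSimulation(genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# annotation

@dataclass
class AnnotationSimulation:
    models: list[GeneModel]
    truth: AnnotationStats
    genome_length: int


def simulate_annotation(config: SimConfig) -> AnnotationSimulation:
    """Gene models whose realized statistics are recorded as truth.

    The truth table is bookkept during generation from the realized
    draws (not from the distribution parameters), so the annotation
    metrics recomputed after a GFF3 round trip must match it exactly.
    """
    cfg = config.annotation
    cfg.validate()
    rng = _rng(config.seed, _TAG_ANNOT)

    def exon_len() -> int:
        mu = np.log(cfg.exon_length_mean) - cfg.exon_length_sigma**2 / 2
        return max(30, int(round(rng.lognormal(mu, cfg.exon_length_sigma))))

    def intron_len() -> int:
        mu = np.log(cfg.intron_length_mean) - cfg.intron_length_sigma**2 / 2
        return max(60, int(round(rng.lognormal(mu, cfg.intron_length_sigma))))

    models: list[GeneModel] = []
    cursor = 0
    n_tx = n_mono = n_utr = 0
    exon_bp = exon_count = intron_bp = intron_count = 0
    span_bp = 0
    cds_coords: list[tuple[int, int]] = []
    tx_counter = 0
    for gi in range(cfg.n_genes):
        cursor += max(200, int(round(rng.exponential(cfg.intergenic_mean))))
        gene_start = cursor
        n_iso = 1 + (1 if rng.random() < cfg.isoform_prob else 0)
        transcripts = []
        gene_end = gene_start
        for _ in range(n_iso):
            tx_counter += 1
            if rng.random() < cfg.monoexonic_fraction:
                n_exons = 1
            else:
                lam = cfg.mean_exons_per_multiexonic - 2
                n_exons = 2 + int(rng.poisson(lam))
            exons = []
            pos = gene_start
            for e in range(n_exons):
                if e > 0:
                    gap = intron_len()
                    intron_bp += gap
                    intron_count += 1
                    pos += gap
                length = exon_len()
                exons.append((pos, pos + length))
                exon_bp += length
                exon_count += 1
                pos += length
            complete = rng.random() < cfg.utr_complete_fraction
            if complete:
                s0, e0 = exons[0]
                sl, el = exons[-1]
                u5 = max(1, min(100, (e0 - s0 - 10) // 2))
                u3 = max(1, min(100, (el - sl - 10) // 2))
                cds = list(exons)
                cds[0] = (s0 + u5, e0)
                cds[-1] = (cds[-1][0], el - u3) if len(cds) > 1 else (s0 + u5, el - u3)
                n_utr += 1
            else:
                cds = list(exons)
            transcripts.append(
                Transcript(
                    f"tx{tx_counter:05d}", exons, cds,
                    has_utr5=complete, has_utr3=complete,
                )
            )
            cds_coords.extend(cds)
            n_tx += 1
            if n_exons == 1:
                n_mono += 1
            gene_end = max(gene_end, exons[-1][1])
        models.append(
            GeneModel(
                id=f"gene{gi + 1:05d}", chrom=cfg.chrom, start=gene_start,
                end=gene_end, strand="+", transcripts=transcripts,
            )
        )
        span_bp += gene_end - gene_start
        cursor = gene_end
    genome_length = cursor + max(200, int(round(rng.exponential(cfg.intergenic_mean))))

    from .annotation import monoexonic_ratio  # avoid top-level name clash

    cds_union = sum(e - s for s, e in merge_coords(cds_coords))
    truth = AnnotationStats(
        n_genes=cfg.n_genes,
        n_transcripts=n_tx,
        n_monoexonic=n_mono,
        monoexonic_ratio_percent=(
            monoexonic_ratio(n_mono, n_tx) if n_mono < n_tx else float("nan")
        ),
        mean_exons_per_transcript=exon_count / n_tx,
        mean_introns_per_transcript=intron_count / n_tx,
        mean_exon_length=exon_bp / exon_count,
        mean_intron_length=intron_bp / intron_count if intron_count else 0.0,
        n_utr_complete=n_utr,
        gene_span_coverage_percent=100.0 * span_bp / genome_length,
        cds_coverage_percent=100.0 * cds_union / genome_length,
    )
    return AnnotationSimulation(
        models=models, truth=truth, genome_length=genome_length
    )
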