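"""Readers and writers for the standard formats every stage touches.

One coordinate convention is used everywhere inside the package: 0-based
half-open. GFF3 (1-based closed on disk) is converted at this boundary;
BED and PAF are already half-open. Parsers report bad lines with line
numbers instead of silently dropping them; recoverable skips are counted
and surfaced on the returned metadata.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .annotation import GeneModel, Transcript
from .intervals import GenomicInterval, interval_union  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """A malformed record, annotated with the file and line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class SeqRecord:
    """A named DNA sequence, uppercased, unknown characters mapped to N."""

    id: str
    sequence: str
    softmasked: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        if set(seq) - _ALPHABET:
            seq = re.sub(r"[^ACGTN]", "N", seq)
        self.sequence = seq
        if not self.sequence:
            raise ValueError(f"sequence {self.id} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment interval between two sequences."""

    query_chrom: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str = "+"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.query_start < 0 or self.target_start < 0:
            raise ValueError("negative alignment coordinate")
        if self.query_start >= self.query_end:
            raise ValueError(
                f"empty query interval {self.query_chrom}:"
                f"{self.query_start}-{self.query_end}"
            )
        if self.target_start >= self.target_end:
            raise ValueError(
                f"empty target interval {self.target_chrom}:"
                f"{self.target_start}-{self.target_end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class FeatureRecord:
    """A generic GFF3-style feature, stored 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    type: str
    id: str | None = None
    parent_id: str | None = None
    attributes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class BedRecord:
    """A BED3-BED6 record; ``name``/``score``/``strand`` optional."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; lowercase (softmask) spans are recorded, then uppercased."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        mask = [
            (m.start(), m.end()) for m in re.finditer(r"[a-z]+", raw)
        ]
        out.append(SeqRecord(rec.id, raw, softmasked=mask))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# PAF

def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read PAF alignment blocks (tab-separated, >= 12 columns).

    Coordinates are 0-based half-open on both query and target; strand is
    column 5. Malformed lines raise :class:`ParseError` naming the line.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    path, lineno, f"PAF line has {len(cols)} columns, need >= 12"
                )
            try:
                qs, qe = int(cols[2]), int(cols[3])
                ts, te = int(cols[7]), int(cols[8])
                score = float(cols[9])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad numeric field: {exc}") from exc
            if min(qs, qe, ts, te) < 0:
                raise ParseError(path, lineno, "negative coordinate")
            strand = cols[4]
            if strand not in "+-":
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            try:
                blocks.append(
                    AlignmentBlock(cols[0], qs, qe, cols[5], ts, te, strand, score)
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock], path: str | Path,
              query_lengths: dict[str, int] | None = None,
              target_lengths: dict[str, int] | None = None) -> None:
    """Write PAF; unknown sequence lengths default to the block end."""
    with open(path, "w") as fh:
        for b in blocks:
            qlen = (query_lengths or {}).get(b.query_chrom, b.query_end)
            tlen = (target_lengths or {}).get(b.target_chrom, b.target_end)
            span = min(b.query_end - b.query_start, b.target_end - b.target_start)
            match = int(b.score) if b.score is not None else span
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_chrom, qlen, b.query_start, b.query_end,
                        b.strand,
                        b.target_chrom, tlen, b.target_start, b.target_end,
                        match, span, 60,
                    )
                )
                + "\n"
            )


_LASTZ_GENERAL_COLUMNS = (
    "name1", "zstart1", "end1", "name2", "strand2", "zstart2+", "end2+", "score"
)


def lastz_general_to_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Convert lastz ``--format=general`` output to alignment blocks.

    Column mapping: name1/zstart1/end1 -> target, name2/strand2/zstart2+/
    end2+ -> query (zstart* are 0-based half-open already), score -> score.
    Provided as a converter only; PAF is the canonical interchange.
    """
    blocks = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        idx = {name: header.index(name) for name in _LASTZ_GENERAL_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.split()
            blocks.append(
                AlignmentBlock(
                    query_chrom=cols[idx["name2"]],
                    query_start=int(cols[idx["zstart2+"]]),
                    query_end=int(cols[idx["end2+"]]),
                    target_chrom=cols[idx["name1"]],
                    target_start=int(cols[idx["zstart1"]]),
                    target_end=int(cols[idx["end1"]]),
                    strand=cols[idx["strand2"]],
                    score=float(cols[idx["score"]]),
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[BedRecord]:
    """Read BED3-BED6 (already 0-based half-open)."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(path, lineno, "BED line has fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(
                    path, lineno, f"non-integer coordinate: {exc}"
                ) from exc
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad score: {exc}") from exc
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else None
            try:
                out.append(BedRecord(cols[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None or r.strand is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None or r.strand is not None:
                cols.append(
                    (f"{r.score:g}" if r.score is not None else ".")
                )
            if r.strand is not None:
                cols.append(r.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gff3_gene_models(path: str | Path) -> tuple[list[GeneModel], dict]:
    """Read GFF3 gene/mRNA/exon/CDS/UTR features into gene models.

    On-disk coordinates (1-based closed) are converted to 0-based
    half-open. Exons without a resolvable parent are skipped with a
    warning; the skip count is returned in the metadata dict.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    models: list[GeneModel] = []
    skipped = 0
    known_tx = {f.id for f in db.features_of_type("mRNA")}
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            cds = []
            has5 = has3 = False
            for child in db.children(mrna, order_by="start"):
                if child.end < child.start:
                    raise ValueError(
                        f"feature end < start at {child.seqid}:{child.start}"
                    )
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    has5 = True
                elif child.featuretype == "three_prime_UTR":
                    has3 = True
            if not exons:
                skipped += 1
                log.warning("transcript %s has no exons; skipped", mrna.id)
                continue
            transcripts.append(
                Transcript(mrna.id, exons, cds, has_utr5=has5, has_utr3=has3)
            )
        models.append(
            GeneModel(
                id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                transcripts=transcripts,
            )
        )
    # orphans: exon/CDS whose Parent is not a known mRNA
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            if not parents or all(p not in known_tx for p in parents):
                skipped += 1
                log.warning("%s at %s:%s has no resolvable parent; skipped",
                            ftype, feat.seqid, feat.start)
    return models, {"skipped": skipped}


def write_gff3_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (1-based closed on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(
                f"{g.chrom}\tslugkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{strand}\t.\tID={g.id}\n"
            )
            for t in g.transcripts:
                ts = min(s for s, _ in t.exons)
                te = max(e for _, e in t.exons)
                fh.write(
                    f"{g.chrom}\tslugkit\tmRNA\t{ts + 1}\t{te}\t.\t{strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tslugkit\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={t.id}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{g.chrom}\tslugkit\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                        f"Parent={t.id}\n"
                    )
                if t.has_utr5:
                    s, e = t.exons[0]
                    fh.write(
                        f"{g.chrom}\tslugkit\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                        f"{strand}\t.\tParent={t.id}\n"
                    )
                if t.has_utr3:
                    s, e = t.exons[-1]
                    fh.write(
                        f"{g.chrom}\tslugkit\tthree_prime_UTR\t{s + 1}\t{e}\t.\t"
                        f"{strand}\t.\tParent={t.id}\n"
                    )


# ---------------------------------------------------------------------------
# TSV helpers

def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence],
              metadata: dict | None = None) -> None:
    """TSV with a header line and '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
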