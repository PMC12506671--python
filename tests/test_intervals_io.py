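"""Interval algebra and format readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slugkit.intervals import (
    GenomicInterval,
    complement_coords,
    interval_union,
    intersect_coords,
    merge_coords,
    subtract_coords,
)
from slugkit.io import (
    AlignmentBlock,
    BedRecord,
    ParseError,
    SeqRecord,
    read_bed,
    read_fasta,
    read_gff3_gene_models,
    read_paf,
    write_bed,
    write_fasta,
    write_gff3_gene_models,
    write_paf,
)


def bitmap_union_length(coords, size):
    """Independent per-base oracle for covered length."""
    bits = np.zeros(size, dtype=bool)
    for s, e in coords:
        bits[s:e] = True
    return int(bits.sum())


class TestIntervalUnion:
    def test_overlapping_pair_merges(self):
        ivs = [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)]
        merged, total = interval_union(ivs)
        assert merged == [GenomicInterval("c", 0, 150)]
        assert total == 150

    def test_empty_input(self):
        assert interval_union([]) == ([], 0)

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chrA.*chrB"):
            interval_union(
                [GenomicInterval("chrA", 0, 5), GenomicInterval("chrB", 0, 5)]
            )

    def test_matches_bitmap_oracle_on_random_intervals(self, rng):
        for _ in range(25):
            starts = rng.integers(0, 9_900, size=200)
            lengths = rng.integers(1, 400, size=200)
            coords = [(int(s), int(min(s + l, 10_000)))
                      for s, l in zip(starts, lengths)]
            ivs = [GenomicInterval("c", s, e) for s, e in coords]
            merged, total = interval_union(ivs)
            assert total == bitmap_union_length(coords, 10_000)
            # disjoint and sorted
            for a, b in zip(merged, merged[1:]):
                assert a.end < b.start or (a.end <= b.start)
            assert total == sum(iv.length for iv in merged)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)),
            max_size=40,
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_idempotent_and_bounded(self, pairs):
        ivs = [GenomicInterval("c", s, s + l) for s, l in pairs]
        merged, total = interval_union(ivs)
        again, total2 = interval_union(merged)
        assert merged == again and total == total2
        assert total <= sum(iv.length for iv in ivs)
        disjoint = all(a.end <= b.start for a, b in zip(merged, merged[1:]))
        # equality iff inputs pairwise disjoint
        if total == sum(iv.length for iv in ivs):
            spans = sorted((s, s + l) for s, l in pairs)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        assert disjoint

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)
        with pytest.raises(ValueError):
            GenomicInterval("c", -1, 5)


class TestCoordAlgebra:
    def test_subtract_and_complement(self):
        assert subtract_coords([(0, 100)], [(20, 30), (50, 60)]) == [
            (0, 20), (30, 50), (60, 100)
        ]
        assert complement_coords(50, [(0, 10), (40, 50)]) == [(10, 40)]

    def test_intersect(self):
        assert intersect_coords([(0, 10), (20, 30)], [(5, 25)]) == [
            (5, 10), (20, 25)
        ]

    def test_algebra_against_bitmap(self, rng):
        for _ in range(50):
            a = [(int(s), int(s + l)) for s, l in
                 zip(rng.integers(0, 900, 30), rng.integers(1, 120, 30))]
            b = [(int(s), int(s + l)) for s, l in
                 zip(rng.integers(0, 900, 30), rng.integers(1, 120, 30))]
            bits_a = np.zeros(1100, dtype=bool)
            bits_b = np.zeros(1100, dtype=bool)
            for s, e in a:
                bits_a[s:e] = True
            for s, e in b:
                bits_b[s:e] = True
            assert sum(e - s for s, e in subtract_coords(a, b)) == int(
                (bits_a & ~bits_b).sum()
            )
            assert sum(e - s for s, e in intersect_coords(a, b)) == int(
                (bits_a & bits_b).sum()
            )


class TestPaf:
    def test_spec_conformant_line(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("q\t1000\t0\t100\t+\tt\t2000\t500\t600\t95\t100\t60\n")
        (block,) = read_paf(p)
        assert (block.query_chrom, block.query_start, block.query_end) == ("q", 0, 100)
        assert (block.target_chrom, block.target_start, block.target_end) == (
            "t", 500, 600
        )
        assert block.strand == "+"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.paf"
        p.write_text("")
        assert read_paf(p) == []

    def test_truncated_line_reports_line_number(self, tmp_path):
        p = tmp_path / "t.paf"
        p.write_text("q\t1000\t0\t100\t+\tt\t2000\t500\t600\t95\t100\t60\n"
                     "q\t1000\t0\t100\n")
        with pytest.raises(ParseError, match=":2:"):
            read_paf(p)

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "n.paf"
        p.write_text("q\t1000\t-5\t100\t+\tt\t2000\t500\t600\t95\t100\t60\n")
        with pytest.raises(ParseError, match="negative"):
            read_paf(p)

    def test_round_trip_identity(self, tmp_path, rng):
        blocks = []
        for _ in range(50):
            qs = int(rng.integers(0, 1000))
            ts = int(rng.integers(0, 1000))
            l = int(rng.integers(1, 500))
            blocks.append(
                AlignmentBlock(
                    f"q{rng.integers(1, 4)}", qs, qs + l,
                    f"t{rng.integers(1, 4)}", ts, ts + l,
                    "+" if rng.random() < 0.5 else "-", float(l),
                )
            )
        p = tmp_path / "rt.paf"
        write_paf(blocks, p)
        assert read_paf(p) == blocks


class TestBed:
    def test_bed3(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n")
        assert read_bed(p) == [BedRecord("chr1", 0, 10)]

    def test_bed6_strand_preserved(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t5\t25\tfeat\t3.5\t-\n")
        (rec,) = read_bed(p)
        assert rec.strand == "-" and rec.name == "feat" and rec.score == 3.5

    def test_non_integer_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t0\t10\nchr1\tx\t20\n")
        with pytest.raises(ParseError, match=":2:"):
            read_bed(p)

    def test_round_trip_identity(self, tmp_path, rng):
        recs = []
        for i in range(100):
            s = int(rng.integers(0, 10_000))
            recs.append(
                BedRecord(
                    f"chr{rng.integers(1, 5)}", s, s + int(rng.integers(1, 500)),
                    f"f{i}", float(rng.integers(0, 100)),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        p = tmp_path / "rt.bed"
        write_bed(recs, p)
        assert read_bed(p) == recs


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1\n"
        "chr1\tsrc\texon\t201\t300\t.\t+\t.\tParent=t1\n"
    )

    def test_coordinate_conversion_and_introns(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        models, meta = read_gff3_gene_models(p)
        (gene,) = models
        (tx,) = gene.transcripts
        assert tx.exons == [(0, 100), (200, 300)]
        assert tx.introns == [(100, 200)]
        assert gene.start == 0 and gene.end == 300
        assert meta["skipped"] == 0

    def test_single_exon_no_introns(self, tmp_path):
        p = tmp_path / "m.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t10\t50\t.\t-\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t10\t50\t.\t-\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t10\t50\t.\t-\t.\tParent=t1\n"
        )
        models, _ = read_gff3_gene_models(p)
        assert models[0].transcripts[0].introns == []

    def test_orphan_exon_counted(self, tmp_path):
        p = tmp_path / "o.gff3"
        p.write_text(self.GFF + "chr1\tsrc\texon\t400\t500\t.\t+\t.\tParent=nope\n")
        _, meta = read_gff3_gene_models(p)
        assert meta["skipped"] == 1

    def test_synthetic_round_trip(self, tmp_path, sim_config):
        from slugkit.simulate import simulate_annotation

        sim = simulate_annotation(sim_config)
        p = tmp_path / "rt.gff3"
        write_gff3_gene_models(sim.models, p)
        models, _ = read_gff3_gene_models(p)
        assert len(models) == len(sim.models)
        for got, want in zip(models, sim.models):
            assert got.id == want.id
            assert (got.chrom, got.start, got.end) == (
                want.chrom, want.start, want.end
            )
            for gt, wt in zip(got.transcripts, want.transcripts):
                assert gt.exons == wt.exons
                assert gt.cds == wt.cds
                assert gt.is_utr_complete == wt.is_utr_complete


class TestFasta:
    def test_round_trip_and_softmask(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGTacgtNNX\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGTACGTNNN"  # uppercased, X -> N
        assert rec.softmasked == [(4, 8)]
        q = tmp_path / "b.fa"
        write_fasta([rec], q)
        assert read_fasta(q)[0].sequence == rec.sequence

    def test_seqrecord_validation(self):
        with pytest.raises(ValueError):
            SeqRecord("x", "")
        assert SeqRecord("x", "acgu").sequence == "ACGT"
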