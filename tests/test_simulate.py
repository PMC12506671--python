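"""Synthetic-data generators: determinism, planted structure, truth."""

import dataclasses

import pytest

from slugkit.intervals import merge_coords, subtract_coords
from slugkit.simulate import (
    AnnotationSimConfig,
    MirnaSimConfig,
    OrthologConfig,
    SimConfig,
    SmallRnaConfig,
    WgdConfig,
    simulate_annotation,
    simulate_mirna_loci,
    simulate_ortholog_table,
    simulate_smallrna_reads,
    simulate_wgd_genome,
)


def cfg_with(seed=7, **sections):
    return SimConfig(seed=seed, **sections)


class TestWgdGenome:
    def test_zero_divergence_limit(self):
        cfg = cfg_with(wgd=WgdConfig(n_ancestral_chroms=2, divergence=0.0))
        sim = simulate_wgd_genome(cfg)
        assert len(sim.genome) == 4
        # truth pairs the two copies of each ancestor
        assert sim.truth.cognate_map == {
            "chr1": ("chr3",), "chr2": ("chr4",),
            "chr3": ("chr1",), "chr4": ("chr2",),
        }
        # blocks cover >= 95% of unmasked length between partners
        for chrom, partners in sim.truth.cognate_map.items():
            covered = merge_coords(
                [(b.query_start, b.query_end) for b in sim.blocks
                 if b.query_chrom == chrom]
                + [(b.target_start, b.target_end) for b in sim.blocks
                   if b.target_chrom == chrom]
            )
            unmasked = sum(
                e - s for s, e in subtract_coords(covered, sim.mask[chrom])
            )
            total_unmasked = sim.truth.chrom_lengths[chrom] - sum(
                e - s for s, e in merge_coords(sim.mask[chrom])
            )
            assert unmasked >= 0.95 * total_unmasked
            assert partners  # every chromosome has a WGD partner

    def test_fusion_plants_telomere_array_and_one_to_two_truth(self):
        cfg = cfg_with(wgd=WgdConfig(n_ancestral_chroms=3, n_fusions=1))
        sim = simulate_wgd_genome(cfg)
        (fused,) = sim.truth.fused_chroms
        partners = sim.truth.cognate_map[fused]
        assert len(partners) == 2  # one-to-two relation
        (junction,) = sim.truth.junctions
        assert junction.chrom == fused
        seq = {r.id: r.sequence for r in sim.genome}[fused]
        array = seq[junction.start:junction.end]
        assert array == "TTAGGG" * (len(array) // 6)
        # the two partners are not each other's partners
        a, b = partners
        assert b not in sim.truth.cognate_map[a]

    def test_fission_splits_one_copy(self):
        cfg = cfg_with(wgd=WgdConfig(n_ancestral_chroms=2, n_fissions=1))
        sim = simulate_wgd_genome(cfg)
        ((p1, p2),) = [sim.truth.fission_pieces[0]]
        # both pieces map back to the same intact copy
        assert sim.truth.cognate_map[p1] == sim.truth.cognate_map[p2]

    def test_same_seed_identical_output(self):
        cfg = cfg_with(seed=11)
        a = simulate_wgd_genome(cfg)
        b = simulate_wgd_genome(cfg)
        assert [r.sequence for r in a.genome] == [r.sequence for r in b.genome]
        assert a.blocks == b.blocks
        assert a.mask == b.mask

    def test_too_many_fusions_rejected(self):
        cfg = cfg_with(wgd=WgdConfig(n_ancestral_chroms=2, n_fusions=2))
        with pytest.raises(ValueError, match="exceed"):
            simulate_wgd_genome(cfg)


class TestSmallRna:
    def test_u1_degenerate_probability(self):
        cfg = cfg_with(
            smallrna=SmallRnaConfig(n_reads=500, u1_prob=1.0,
                                    pingpong_fraction=0.0)
        )
        sim = simulate_smallrna_reads(cfg)
        assert all(r.sequence[0] == "U" for r in sim.reads)

    def test_planted_pingpong_pairs_equal_bruteforce_count(self):
        cfg = cfg_with(
            smallrna=SmallRnaConfig(n_reads=20_000, pingpong_fraction=0.3)
        )
        sim = simulate_smallrna_reads(cfg)
        # brute-force enumeration of exact-10 5' overlaps
        by_chrom = {}
        for r in sim.reads:
            by_chrom.setdefault(r.chrom, ([], []))[0 if r.strand == "+" else 1].append(r)
        pairs = 0
        for plus, minus in by_chrom.values():
            starts = {}
            for p in plus:
                starts.setdefault(p.start, []).append(p)
            for m in minus:
                for p in starts.get(m.end - 10, []):
                    if 10 <= min(p.length, m.length):
                        pairs += 1
        assert pairs == sim.truth.n_secondary == round(20_000 * 0.3)

    def test_same_seed_identical_reads(self):
        cfg = cfg_with(seed=5)
        assert simulate_smallrna_reads(cfg).reads == simulate_smallrna_reads(cfg).reads

    def test_reads_respect_length_range(self):
        cfg = cfg_with(smallrna=SmallRnaConfig(n_reads=2_000))
        sim = simulate_smallrna_reads(cfg)
        assert all(18 <= r.length <= 32 for r in sim.reads)

    def test_cluster_too_long_rejected(self):
        cfg = cfg_with(
            smallrna=SmallRnaConfig(cluster_length=2_000_000,
                                    chrom_length=1_000_000)
        )
        with pytest.raises(ValueError, match="longer than"):
            simulate_smallrna_reads(cfg)


class TestMirnaLoci:
    def test_exact_reference_copy_is_high(self, sim_config):
        sim = simulate_mirna_loci(sim_config)
        ref_matures = {r.mature for r in sim.references}
        exact = [l for l in sim.loci if l.mature_main in ref_matures
                 and not l.any_artifact_flag]
        assert exact and all(sim.truth[l.id] == "high" for l in exact)

    def test_scrambled_low_expression_is_ambiguous(self, sim_config):
        sim = simulate_mirna_loci(sim_config)
        ambiguous = [l for l in sim.loci if sim.truth[l.id] == "ambiguous"]
        assert ambiguous
        assert all(
            l.max_rpm < 1.0 or l.five_prime_homogeneity < 0.75
            for l in ambiguous
        )

    def test_same_seed_identical(self):
        cfg = cfg_with(seed=3)
        a = simulate_mirna_loci(cfg)
        b = simulate_mirna_loci(cfg)
        assert [(l.id, l.precursor, l.rpm_per_sample) for l in a.loci] == [
            (l.id, l.precursor, l.rpm_per_sample) for l in b.loci
        ]

    def test_class_counts_respected(self):
        counts = {"high": 10, "moderate": 8, "ambiguous": 6, "artifact": 4}
        cfg = cfg_with(mirna=MirnaSimConfig(class_counts=counts))
        sim = simulate_mirna_loci(cfg)
        got = {c: sum(1 for v in sim.truth.values() if v == c) for c in counts}
        assert got == counts


class TestOrthologTable:
    def test_planted_cluster_has_identical_sets(self, sim_config):
        sim = simulate_ortholog_table(sim_config)
        by_id = {g.id: g for g in sim.genes}
        members = [by_id[m] for m in sim.truth.clusters[0]]
        sets = {g.ortholog_set for g in members}
        assert len(sets) == 1  # all pairwise jaccards are 1

    def test_bruteforce_jaccard_recovers_exactly_planted_edges(self, sim_config):
        from slugkit.paralogs import jaccard_similarity

        sim = simulate_ortholog_table(sim_config)
        found = set()
        genes = sim.genes
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if jaccard_similarity(a.ortholog_set, b.ortholog_set) > 0.5:
                    found.add(tuple(sorted((a.id, b.id))))
        assert found == sim.truth.edges

    def test_nonplanted_jaccards_below_cap(self, sim_config):
        from slugkit.paralogs import jaccard_similarity

        sim = simulate_ortholog_table(sim_config)
        genes = sim.genes
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                pair = tuple(sorted((a.id, b.id)))
                if pair not in sim.truth.edges:
                    assert jaccard_similarity(a.ortholog_set, b.ortholog_set) <= 0.2

    def test_same_seed_identical_tables(self):
        cfg = cfg_with(seed=9)
        a = simulate_ortholog_table(cfg)
        b = simulate_ortholog_table(cfg)
        assert a.genes == b.genes

    def test_undersized_gene_count_rejected(self):
        cfg = cfg_with(orthologs=OrthologConfig(n_genes=30))
        with pytest.raises(ValueError, match="n_genes"):
            simulate_ortholog_table(cfg)


class TestAnnotationSim:
    def test_monoexonic_fraction_zero(self):
        cfg = cfg_with(annotation=AnnotationSimConfig(monoexonic_fraction=0.0))
        sim = simulate_annotation(cfg)
        assert sim.truth.n_monoexonic == 0

    def test_utr_complete_fraction_one(self):
        cfg = cfg_with(annotation=AnnotationSimConfig(utr_complete_fraction=1.0))
        sim = simulate_annotation(cfg)
        assert sim.truth.n_utr_complete == sim.truth.n_transcripts

    def test_truth_matches_recomputed_stats_exactly(self, sim_config):
        from slugkit.annotation import transcript_stats

        cfg = dataclasses.replace(
            sim_config, annotation=AnnotationSimConfig(n_genes=40)
        )
        sim = simulate_annotation(cfg)
        stats = transcript_stats(sim.models)
        assert stats.n_transcripts == sim.truth.n_transcripts
        assert stats.mean_exon_length == pytest.approx(
            sim.truth.mean_exon_length, abs=1e-9
        )
        assert stats.mean_intron_length == pytest.approx(
            sim.truth.mean_intron_length, abs=1e-9
        )
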