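"""End-to-end demonstration run over synthetic data.

``run_demo`` simulates a WGD genome, a small-RNA population, an
ortholog table and an annotation bundle, runs every analysis stage on
them, writes per-stage reports into an output directory, and returns a
summary comparing the recovered values against the planted truth. The
individual ``demo_*`` helpers are importable so scripted reproduction
runs can call single stages.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Any

import yaml

from . import annotation as ann
from . import cognate as cog
from . import mirna as mir
from . import paralogs as par
from . import pirna as pir
from . import smallrna as srn
from . import telomeres as tel
from .intervals import merge_coords
from .io import write_fasta, write_gff3_gene_models, write_paf, write_tsv
from .simulate import (
    SimConfig,
    simulate_annotation,
    simulate_mirna_loci,
    simulate_ortholog_table,
    simulate_smallrna_reads,
    simulate_wgd_genome,
)

log = logging.getLogger(__name__)

PIRNA_LEN = (27, 30)


def chrom_summaries(sim) -> list[cog.ChromSummary]:
    """Per-chromosome length/mask summaries from a WGD simulation."""
    lengths = sim.chrom_lengths()
    return [
        cog.ChromSummary(
            chrom=c,
            length=lengths[c],
            masked=sum(e - s for s, e in merge_coords(sim.mask.get(c, []))),
        )
        for c in sorted(lengths)
    ]


def demo_cognate(config: SimConfig) -> dict[str, Any]:
    """No-rearrangement WGD recovery: fraction of chromosomes whose
    assigned cognate is a planted partner."""
    sim = simulate_wgd_genome(config)
    chroms = chrom_summaries(sim)
    cov = cog.partner_coverage(sim.blocks, chroms, sim.mask, clip_to_unmasked=True)
    assignments = cog.cognate_scores(cov, chroms)
    correct = sum(
        1 for a in assignments if a.cognate in sim.truth.cognate_map[a.chrom]
    )
    return {
        "sim": sim,
        "assignments": assignments,
        "chroms": chroms,
        "n_chroms": len(assignments),
        "recovery_percent": 100.0 * correct / len(assignments)
        if assignments else 0.0,
    }


def demo_fusion(config: SimConfig) -> dict[str, Any]:
    """Fusion scenario: the fused chromosome must be the cognate of both
    ancestral partners, which are not cognates of each other."""
    fus_cfg = dataclasses.replace(config.wgd, n_fusions=1)
    cfg = dataclasses.replace(config, wgd=fus_cfg)
    sim = simulate_wgd_genome(cfg)
    chroms = chrom_summaries(sim)
    cov = cog.partner_coverage(sim.blocks, chroms, sim.mask)
    assignments = {a.chrom: a for a in cog.cognate_scores(cov, chroms)}
    fused = sim.truth.fused_chroms[0]
    partners = sorted(sim.truth.cognate_map[fused])
    b, c = partners[0], partners[1]
    pattern_ok = (
        assignments[b].cognate == fused
        and assignments[c].cognate == fused
        and assignments[fused].cognate in partners
        and assignments[b].cognate != c
        and assignments[c].cognate != b
    )
    return {
        "sim": sim,
        "assignments": assignments,
        "fused": fused,
        "partners": partners,
        "pattern_ok": pattern_ok,
    }


def demo_smallrna(config: SimConfig) -> dict[str, Any]:
    """Length/composition/overlap statistics on a simulated read set."""
    sim = simulate_smallrna_reads(config)
    reads = srn.filter_by_length(sim.reads, 18, 32)
    hist = srn.length_histogram([reads])
    pirna_reads = srn.filter_by_length(reads, *PIRNA_LEN)
    pfm = srn.position_frequency_matrix(pirna_reads, k=10)
    overlap = srn.five_prime_overlap_distribution(pirna_reads)
    return {
        "sim": sim,
        "reads": reads,
        "pirna_reads": pirna_reads,
        "histogram": hist,
        "modal_length": int(hist.mean.idxmax()),
        "pfm": pfm,
        "u1_fraction": pfm.u1_fraction,
        "overlap": overlap,
        "overlap_argmax": overlap.argmax,
        "overlap_z10": overlap.z_score(10),
    }


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(
        inter / (a[1] - a[0]) if a[1] > a[0] else 0.0,
        inter / (b[1] - b[0]) if b[1] > b[0] else 0.0,
    )


def demo_pirna(config: SimConfig, smallrna_result: dict | None = None) -> dict[str, Any]:
    """Cluster calling, merge, ranking; recall against planted clusters
    at >= 50% reciprocal overlap."""
    res = smallrna_result or demo_smallrna(config)
    sim = res["sim"]
    called = pir.call_clusters_density(res["pirna_reads"])
    merged = pir.merge_adjacent(called)
    ranked = pir.rank_and_cumulative(merged, total_mapped_reads=len(res["reads"]))
    recalled = 0
    for iv, _orientation in sim.truth.clusters:
        for c in merged:
            if c.chrom == iv.chrom and _reciprocal_overlap(
                (c.start, c.end), (iv.start, iv.end)
            ) >= 0.5:
                recalled += 1
                break
    return {
        "called": called,
        "merged": merged,
        "ranked": ranked,
        "recall_percent": 100.0 * recalled / len(sim.truth.clusters),
        "top_n_90": pir.top_n_for_fraction(ranked, 0.90),
    }


def demo_mirna(config: SimConfig) -> dict[str, Any]:
    """Curation recovery over the simulated locus battery."""
    sim = simulate_mirna_loci(config)
    curated = mir.curate(sim.loci, sim.references)
    agree = sum(1 for l in curated if l.confidence == sim.truth[l.id])
    return {
        "sim": sim,
        "curated": curated,
        "n_loci": len(curated),
        "agreement_percent": 100.0 * agree / len(curated) if curated else 0.0,
    }


def demo_paralogs(config: SimConfig) -> dict[str, Any]:
    """Link and cluster recovery on the planted ortholog table."""
    sim = simulate_ortholog_table(config)
    edges = par.build_paralog_links(sim.genes, threshold=0.5)
    found = {(e.gene_a, e.gene_b) for e in edges}
    clusters = par.detect_gene_clusters(sim.genes, edges)
    cluster_sets = {frozenset(c.members) for c in clusters}
    truth_sets = {frozenset(m) for m in sim.truth.clusters}
    conn = par.chromosome_connection_counts(edges, sim.genes)
    return {
        "sim": sim,
        "edges": edges,
        "clusters": clusters,
        "connection_counts": conn,
        "edges_exact": found == sim.truth.edges,
        "edge_recovery_percent": (
            100.0 * len(found & sim.truth.edges) / len(sim.truth.edges)
            if sim.truth.edges else 100.0
        ),
        "clusters_exact": cluster_sets == truth_sets,
    }


def demo_annotation(config: SimConfig, workdir: Path | None = None) -> dict[str, Any]:
    """GFF3 round trip: generated models -> file -> parsed stats vs truth."""
    import tempfile

    sim = simulate_annotation(config)
    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            gff = Path(tmp) / "annotation.gff3"
            write_gff3_gene_models(sim.models, gff)
            from .io import read_gff3_gene_models

            models, _meta = read_gff3_gene_models(gff)
    else:
        gff = workdir / "annotation.gff3"
        write_gff3_gene_models(sim.models, gff)
        from .io import read_gff3_gene_models

        models, _meta = read_gff3_gene_models(gff)
    stats = ann.transcript_stats(models)
    span_cov, cds_cov = ann.genome_coverage(models, sim.genome_length)
    return {
        "sim": sim,
        "models": models,
        "stats": stats,
        "span_coverage_percent": span_cov,
        "cds_coverage_percent": cds_cov,
        "counts_match": (
            stats.n_genes == sim.truth.n_genes
            and stats.n_transcripts == sim.truth.n_transcripts
            and stats.n_monoexonic == sim.truth.n_monoexonic
            and stats.n_utr_complete == sim.truth.n_utr_complete
        ),
        "mean_exon_error": abs(stats.mean_exon_length - sim.truth.mean_exon_length),
        "mean_intron_error": abs(
            stats.mean_intron_length - sim.truth.mean_intron_length
        ),
    }


def demo_telomeres(fusion_result: dict) -> dict[str, Any]:
    """Fusion-junction arrays must scan as TTAGGG tandem arrays and
    classify as interstitial."""
    sim = fusion_result["sim"]
    lengths = sim.chrom_lengths()
    seqs = {r.id: r.sequence for r in sim.genome}
    arrays = [
        tel.TandemArray(j.chrom, j.start, j.end,
                        sequence=seqs[j.chrom][j.start:j.end])
        for j in sim.truth.junctions
    ]
    report = tel.annotate_arrays(arrays, lengths)
    return {
        "arrays": arrays,
        "report": report,
        "all_interstitial": bool((report["position_class"] == "interstitial").all()),
        "motif_fwd_total": int(report["motif_fwd"].sum()),
    }


def run_demo(seed: int, outdir: str | Path, config: SimConfig | None = None) -> dict:
    """Simulate every input, run every stage, write per-stage reports.

    Returns the summary mapping; also writes ``summary.tsv`` comparing
    recovered values against simulation truth, and a resolved copy of
    the configuration next to the outputs.
    """
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SimConfig(seed=seed)
    if cfg.seed != seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    summary: dict[str, Any] = {"seed": seed}

    stage = "cognate"
    try:
        cg = demo_cognate(cfg)
        write_fasta(cg["sim"].genome, out / "wgd_genome.fasta")
        write_paf(cg["sim"].blocks, out / "wgd_selfalign.paf")
        cog.cognate_table(cg["assignments"], out / "cognate.tsv", cg["chroms"])
        summary["cognate_recovery_percent"] = cg["recovery_percent"]

        stage = "fusion"
        fus = demo_fusion(cfg)
        summary["fusion_pattern_ok"] = fus["pattern_ok"]

        stage = "telomeres"
        tl = demo_telomeres(fus)
        tl["report"].to_csv(out / "telomere_arrays.tsv", sep="\t", index=False)
        summary["junction_arrays_interstitial"] = tl["all_interstitial"]

        stage = "smallrna"
        sr = demo_smallrna(cfg)
        sr["histogram"].per_replicate.assign(mean=sr["histogram"].mean).to_csv(
            out / "length_histogram.tsv", sep="\t"
        )
        sr["pfm"].to_frame().to_csv(out / "position_frequencies.tsv", sep="\t")
        sr["overlap"].counts.rename("pairs").to_csv(out / "overlap.tsv", sep="\t")
        summary["modal_read_length"] = sr["modal_length"]
        summary["u1_fraction"] = sr["u1_fraction"]
        summary["overlap_argmax"] = sr["overlap_argmax"]
        summary["overlap_z10"] = sr["overlap_z10"]

        stage = "pirna"
        pi = demo_pirna(cfg, sr)
        write_tsv(
            out / "pirna_clusters.tsv",
            ["chrom", "start", "end", "orientation", "reads", "rpm", "rank",
             "cumulative_fraction"],
            [
                (c.chrom, c.start, c.end, c.orientation, c.read_count,
                 round(c.rpm, 3), c.rank, round(c.cumulative_fraction, 5))
                for c in pi["ranked"]
            ],
            metadata={"top_n_for_0.90": pi["top_n_90"]},
        )
        summary["pirna_cluster_recall_percent"] = pi["recall_percent"]
        summary["pirna_top_n_90"] = pi["top_n_90"]

        stage = "mirna"
        mi = demo_mirna(cfg)
        write_tsv(
            out / "mirna_curation.tsv",
            ["locus", "match_class", "hairpin_paired_fraction", "max_rpm",
             "homogeneity", "confidence", "truth", "family"],
            [
                (l.id, l.match_class, round(l.hairpin_paired_fraction, 3),
                 round(l.max_rpm, 2), round(l.five_prime_homogeneity, 3),
                 l.confidence, mi["sim"].truth[l.id], l.family or ".")
                for l in mi["curated"]
            ],
        )
        summary["mirna_agreement_percent"] = mi["agreement_percent"]

        stage = "paralogs"
        pl = demo_paralogs(cfg)
        write_tsv(
            out / "paralog_edges.tsv",
            ["gene_a", "gene_b", "jaccard", "relation"],
            [(e.gene_a, e.gene_b, round(e.jaccard, 4), e.relation)
             for e in pl["edges"]],
            metadata={"threshold": 0.5},
        )
        pl["connection_counts"].to_csv(out / "chrom_connections.tsv", sep="\t")
        summary["paralog_edge_recovery_percent"] = pl["edge_recovery_percent"]
        summary["paralog_clusters_exact"] = pl["clusters_exact"]

        stage = "annotation"
        an = demo_annotation(cfg, workdir=out)
        summary["annotation_counts_match"] = an["counts_match"]
        summary["mean_exon_length_bp"] = an["stats"].mean_exon_length
        summary["monoexonic_ratio_percent"] = an["stats"].monoexonic_ratio_percent

        stage = "assembly"
        lengths = list(cg["sim"].chrom_lengths().values())
        st = ann.assembly_stats(lengths)
        summary["assembly_n50_bp"] = st.nx[50]
        summary["assembly_l50"] = st.lx[50]
    except Exception as exc:
        log.error("demo stage %r failed: %s", stage, exc)
        raise RuntimeError(f"demo stage {stage!r} failed: {exc}") from exc

    summary["wall_time_s"] = round(time.time() - t0, 2)
    write_tsv(
        out / "summary.tsv",
        ["quantity", "value"],
        sorted(summary.items()),
    )
    log.info("demo complete in %.1fs -> %s", summary["wall_time_s"], out)
    return summary
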