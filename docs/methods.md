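# Methods

This note documents the models, rules and numerical choices behind
slugkit, what the synthetic-data generators emulate, and what passing
tests do and do not establish about real data.

## Coordinate and sequence conventions

All coordinates inside the package are 0-based half-open. GFF3 (1-based
closed on disk) is converted at the parser boundary; BED and PAF are
already half-open. PAF is the canonical alignment interchange: the
aligner itself is out of scope, and a converter from lastz
`--format=general` columns is provided for teams arriving from that
tool. DNA is uppercased with unknown characters mapped to N; softmasked
(lowercase) spans are recorded as a mask track on reading FASTA. RNA
handling treats U and T as equivalent.

## Cognate chromosomes

score(i, j) = ℓ(i,j) / (L_i − M_i), with ℓ(i,j) the union length of
bases of chromosome i covered by alignment blocks partnered with j.
Choices where the definition is underdetermined:

- **Both block directions contribute** (i as query and i as target):
  an all-vs-all self-alignment makes direction arbitrary.
- **Self-partner blocks (query chrom == target chrom) are excluded
  wholesale**; the statistic quantifies inter-chromosomal homology
  only. Intra-chromosomal duplication belongs to the paralog map.
- **Coverage is clipped to unmasked bases by default**, making
  score ≤ 1 a checkable invariant even on unmasked synthetic input
  (alignments of a hardmasked genome cannot cover masked bases anyway);
  `clip_to_unmasked=False` / `--no-clip` restores raw behaviour.
- **Ties** break by larger raw ℓ, then lexicographic chromosome id;
  all tied partners are reported. Chromosomes with zero effective
  length are excluded with a logged reason rather than crashing.
- Unplaced scaffolds can serve as partners but receive no assignment of
  their own unless requested (`--include-unplaced`).

## Paralog map

Jaccard similarity is 0 when both sets are empty. The link threshold
defaults to 0.5 and is always echoed in output metadata; gene-pair
distance is measured between interval midpoints. Cluster construction
chains each connected component of the link graph positionally: a run
extends while the next member starts within the 5 Mb window of the
previous one and the total span (max end − min start) stays ≤ 5 Mb;
runs of ≥ 5 members are reported. Putative segmental duplications are
the intra-near (≤ 5 Mb) link pairs, with the same window as a flag.

## Small-RNA statistics

- The length filter is inclusive on both bounds (18 and 32 kept).
- Replicate histograms average *fractions*, not pooled counts, so each
  biological replicate weighs equally regardless of depth.
- Position frequencies are read-count weighted, in 5′→3′ read
  orientation; N bases never enter a position's denominator.
- 5′ overlap between a plus read p and minus read m on one chromosome
  is k = end_m − start_p (half-open coordinates), contributing
  count_p × count_m to bin k when 1 ≤ k ≤ min(len_p, len_m, k_max=25).
  Pair counting is exhaustive within k_max with no deduplication beyond
  multiplicity weighting; a `--unique`/`weight_by_count=False` switch
  ignores multiplicities. The auxiliary z-score at k = 10 uses the
  mean/sd of the other bins.

## piRNA clusters

The density caller is deliberately simple plumbing, not a
re-implementation of dedicated cluster-annotation tools: reads are
binned by 5′-start into fixed windows (1 kb), runs of consecutive
windows holding ≥ 10 weighted reads become one cluster spanning its
reads, and orientation is plus/minus at ≥ 75% strand bias, else
bidirectional. Its parameters matter only through planted-truth recall.
The merge rule is read literally: gap = next.start − prev.end with a
strict `< 5000` comparison; only identically oriented clusters merge;
bidirectional clusters never merge with stranded ones unless
`--merge-bidirectional` is set; read counts are conserved and the
result is a fixed point. The cumulative-fraction denominator is the sum
of *cluster* RPM values (the fraction of cluster-mapping piRNAs), not
all mapped reads; ties in RPM rank by (chrom, start).

## miRNA curation

Classification precedence: artifact → high → moderate → ambiguous.

- artifact: any of repeat overlap, low complexity, abundant-piRNA
  overlap — these dominate every other signal, including an exact
  reference match.
- high: exact full-length match to a reference mature, OR max RPM ≥ 100
  with 5′ homogeneity ≥ 0.75, a detected passenger strand and a passing
  hairpin. The 100 RPM "abundant" floor reuses the moderate-class
  ceiling; both are configurable and echoed in output metadata.
- moderate: passing hairpin, homogeneity ≥ 0.75, and max RPM in
  [floor, 100), where the floor is 20 RPM for seed-matching candidates
  (positions 2–10 or 2–8 identical to a reference) and 1 RPM otherwise.
  The moderate rule's seed-match sentence admits a second reading in
  which 20 RPM is a *ceiling* for seed-matching candidates; that
  reading is implemented behind `seed_rpm_as_ceiling` /
  `--seed-rpm-ceiling`, with the floor reading as the default.
- ambiguous: everything else (very low expression, diffuse 5′ end, or
  no predictable stem loop).

"Well-defined 5′ end" is quantified as ≥ 0.75 of reads sharing the
modal 5′ position; passenger detection is accepted as an input flag
(no read-pileup rule is imposed). Hairpin plausibility uses maximum
base pairing (Nussinov DP; pairs A-U, G-C, G-U; minimum loop 3) rather
than thermodynamic folding: deterministic and dependency-free. The
statistic is the fraction of mature-arm positions paired to positions
*outside* the arm, passing at ≥ 0.55; the traceback prefers pairing the
leftmost base with its outermost admissible partner, which recovers the
full stem (fraction 1.0) on clean hairpins whenever optima tie.

**Known limitation.** Maximum-matching folds random RNA heavily, so the
0.55 threshold separates planted hairpins (fraction ≈ 1) from
composition-preserving shuffles only in the majority of cases (about
60% of shuffles fail, measured over fixed-seed batteries), not almost
always. The classifier does not lean on this: loci whose truth class is
"ambiguous" in the simulator carry very low expression or diffuse 5′
ends alongside scrambled precursors, as real ambiguous candidates
typically do, and classification recovery is insensitive to hairpin
leakage. Users needing a sharper fold filter should gate on
thermodynamic folding upstream.

## Telomere scan

Motif counting is non-overlapping and greedy left-to-right, separately
for the motif and its reverse complement (a 12-mer TTAGGGTTAGGG counts
2); this matters only for degenerate motifs. The motif defaults to
TTAGGG, with the 5-mer TTAGG variant available via `--motif-both` since
both appear in the field's figure legends. "Terminal" means any part of
the array lies within 100 kb of a chromosome end — "subtelomeric" has
no standard cutoff, so the window is configurable. GC is computed over
non-N bases; the genome-average reference defaults to 42%. Density
tracks tile from position 0 (last window may be short); fraction mode
is union-based per class, count mode assigns a feature to the window
holding its start.

## Annotation and assembly metrics

Mean exon/intron lengths pool all exons/introns (total bp / total
count), not per-transcript means of means. The monoexonic ratio is
100·m/(t−m), reported rounded half-up to 2 decimals (full precision
retained internally; other means report at 1 decimal in the CLI). A
gene's span is its own feature interval when present, else the min/max
over its transcripts. Nx is the length at which descending cumulative
length first reaches x% of the total; Lx the number of sequences
needed.

## Synthetic-data generators

All generators are pure functions of the configuration (seed included);
identical configuration yields byte-identical output, from one named
numpy Generator per section (no global RNG state).

**WGD genome** (defaults: 3 ancestral chromosomes × 200 kb, 5%
per-base divergence, 10% masked fraction). Each ancestral chromosome is
emitted twice, mutated independently by uniform substitution (a
Jukes–Cantor-style model; indels and rate heterogeneity are not
modelled). Fusions join the second copies of two ancestors with a
TTAGGG array (50 copies) at the junction; fissions split a second copy
at its midpoint. Alignment blocks are emitted directly from the known
homology map — partitioned into ≤ 50 kb pieces with ±5% boundary
jitter, each dropped with probability equal to the divergence — so the
cognate stage is tested independently of any third-party aligner. The
divergence default sits in the low single digits to tens of percent
plausible for post-WGD paralogous chromosomes; recovery is verified up
to 10%. Masks are uniformly placed 2 kb segments; junction arrays are
masked as tandem repeats.

**Small-RNA reads** (defaults: 20,000 reads, length ~ round
N(29, 1) clipped to [18, 32], 1U probability 0.8, ping-pong fraction
0.2, 10A probability 0.7, 20 clusters × 5 kb on 4 × 1 Mb chromosomes,
5% background). Primary reads fall inside single-orientation clusters;
secondaries sit on the opposite strand with 5′ ends overlapping a
sampled primary by exactly 10 nt. Multiplicities are modelled by
repeating identical records; collapsing is the profiler's job. Two
placement guarantees make truth exact rather than approximate: 5′
positions are unique per (chromosome, strand), and background reads are
rejection-sampled away from any position that would create a
coincidental exact-10 pair — so the brute-force exact-10 pair count
equals the planted secondary count. Background reads can take a lower
1U probability (`background_u1_prob`) to plant the cluster-restricted
1U enrichment seen in real piRNA data. Sequencing errors and multimap
ambiguity are not simulated; real libraries will show noisier
composition signals than these tests exercise.

**miRNA loci.** Per-class exemplar populations with deliberately clear
margins: high loci get perfect hairpins (≤ 2 planted mismatches), RPM
well above 100 or verbatim reference matures; moderate loci sit in
[25, 90] RPM (seed-matching) or [2, 90]; ambiguous loci combine
scrambled precursors or diffuse 5′ ends with sub-1 RPM expression;
artifact loci cycle through the overlap flags. Real curation deals with
borderline loci these margins avoid — the ≥ 95% recovery criterion
demonstrates rule correctness, not robustness at thresholds.

**Ortholog tables** (400 genes, 6 chromosomes in 3 cognate pairs, 4
planted clusters of 5 within 2 Mb, 30% of genes in WGD pairs). Planted
clusters share identical ortholog sets; WGD pairs share identical or
3-of-5 sets (jaccard 1 or 0.6, both above the 0.5 threshold); all other
genes get disjoint sets, so recovery is exact by construction.

**Annotation** (120 genes, 15% monoexonic, ~8 exons per multiexonic
transcript, lognormal exon/intron lengths with means 250/1500 bp, 45%
UTR-complete, 20% of genes with a second isoform). Truth statistics
are bookkept from the realized draws during generation — an
independent code path from parse→model→statistics — so the GFF3
round trip must reproduce them exactly, not within tolerance.

## Problem sizes and tolerances

The test suite and reproduction script run at desk scale: 200 kb
chromosomes, 10–20 k reads, 100–400 loci, 20-seed batteries. These
sizes were chosen so every oracle (per-base bitmaps, all-pairs
enumerations, exhaustive scans) remains exact and fast; the statistics
themselves are linear or near-linear in their inputs and scale to
chromosome-level genomes. Floating-point comparisons in tests use 1e-9
absolute tolerance where exactness is the claim (fraction sums,
round-trip means); stochastic recovery criteria (binomial 3·SE for the
1U fraction, ≥ 95% detection across seeds, ≥ 90% cluster recall) are
evaluated over fixed-seed batteries.
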