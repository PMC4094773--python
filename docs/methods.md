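# Methods

This note documents the models, rules and numerical choices behind
`nbipscan`, in the spirit of a statistical-software methods appendix. It
states no empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open. GTF (Ensembl dialect,
1-based inclusive) converts at the I/O boundary; BED and bedGraph are
native. Readers stream line-by-line and report the offending line number on
malformed input; writers sort by (chromosome, start) so repeated runs are
byte-identical. Chromosome names must match exactly; readers accept a
`chr_mode` of `strip`/`add` to normalise a leading `chr` because silent
name mismatch is the classic failure mode of multi-source genomics
pipelines.

## Transcript classification

Contigs merge transitively when their spans overlap by ≥ 1 nt on one strand
of one chromosome (a sweep over sorted spans; cluster ids are assigned in
genomic order so the result is independent of input order). Known/novel
status is span-level against annotated gene spans on the same strand, with
a single nucleotide of overlap sufficient. Span-level (rather than
exon-level) overlap is used deliberately: clusters partially inside introns
of a gene they touch belong to that gene's locus, and the downstream
intergenic/antisense analyses are span-based.

### Novel elements of annotated genes

"Sharing an exon" means an exact boundary match of at least one cluster
block with an annotated exon — the element definitions are anchored on
annotated exon boundaries. Rules:

- *novel internal exon*: shared exon plus an extra block fully inside an
  intron of the same transcript;
- *novel donor/acceptor*: a block sharing exactly one boundary with an
  annotated **internal** exon, the novel boundary lying outside the exon
  (a block ending early inside an exon is not a novel boundary) and flanked
  by canonical GT / AG in transcript orientation — on the minus strand the
  genomic reverse complement is checked (AC before a genomic-start donor
  boundary, CT after a genomic-end acceptor boundary);
- *UTR extensions*: the cluster span extends past the annotated terminus by
  ≥ 100 nt (`min_utr_ext`).

Validation is evidence attachment, not filtering: exact block reproduction
(splice elements) or ≥ 50 % reciprocal span overlap (extensions) in an
alternate cluster set; an H3K4me3 peak within 2,000 nt of a novel 5′ end;
a polyA site within 2,000 nt of a novel 3′ end. Assembly itself is out of
scope — any second cluster set serves as the "alternate assembly".

## Sense/antisense pairs

Geometry is decided by which termini meet. For overlapping spans, mutual
containment of the two 5′ (3′) termini in the partner span gives
head-to-head (tail-to-tail); if both hold (near-coextensive genes), the
closer terminus pair wins; nested genes get no geometry. For disjoint
spans the two facing boundaries must both be 5′ (3′) ends. Pairs require
mean expression ≥ 0.1 RPKM per member, and loci where more than two genes
share one overlap pattern are removed entirely (degree > 1 in the
pattern's pair graph).

Junction support: a junction whose one end exactly matches an annotated
splice site of gene G and whose other end falls inside a novel cluster on
the same strand links that cluster to G (a ±2 nt slack is available but off
by default; exact matching mirrors the requirement that junctions match
annotated splice sites). The null expectation for the number of such links
relocates clusters uniformly into intergenic space, preserving
per-chromosome and per-strand counts, and reports the empirical p as
(1 + #null ≥ observed)/(n + 1).

Correlation contrast: Pearson r of log2(RPKM + 0.1) across samples; controls
are nearest non-overlapping opposite-strand gene pairs (midpoint distance,
lower-coordinate tie-break). Densities are Gaussian KDEs with Silverman's
bandwidth, renormalised to integrate to 1 on the grid [−1, 1]; the
difference band holds 100 bootstrap subsamples of the controls at the pair
count. Bootstrap (with replacement) rather than subsampling keeps the band
meaningful when the control pool is no larger than the pair set.

## Genomic context and promoter typing

Intergenic novel clusters (no gene-span overlap on either strand, mean
expression ≥ 0.1 RPKM) are assigned to upstream/downstream × sense/antisense
relative to the nearest gene within the distance cutoff (default 4,000 nt;
orientation in the partner gene's reading direction). The cutoff can be
estimated as the largest grid distance (250-nt steps) at which the observed
near-gene pair count beats 1,000 random intergenic placements at empirical
p < 0.05.

Correlation excess per category compares the observed r distribution with
200 permutations of the cluster–gene pairing, counting permutations beaten
by a one-sided Wilcoxon rank-sum test at p < 0.05; pair-level significance
is Pearson p < 0.05 after Benjamini–Hochberg within the category.

Promoter classes follow the precedence KBiP > NBiP > UniP (an annotated
partner defines the promoter as known; novelty of the partner defines
NBiP). Head-to-head membership requires TSS-to-TSS ≤ `bidir_window`
(default 2,000 nt; "within 2 kb of the TSS" is read as TSS-to-TSS distance).
The NBiP partner position is the cluster's assembled 5′ boundary — assembly
5′-truncation is exactly why the window defaults to 2 kb rather than 1 kb,
and the window is configurable for the 1-kb sensitivity analysis. UniP
requires an empty 5-kb upstream window (no annotated span, no cluster
span). A gene simultaneously UniP-eligible and carrying a head-to-head
partner indicates an annotation conflict and raises. Mutually paired KBiP
genes yield one promoter call anchored at the protein-coding gene (lower
TSS for pc–pc and lnc–lnc pairs); a gene whose chosen partner prefers a
different gene keeps its own call.

The CAGE window is the span between the paired TSSs grown to a total of
`bidir_window` centred on their midpoint (TSS ± window/2 for UniPs), since
"a 2-kb region surrounding the TSS" does not fix sidedness. Divergent:
≥ 1 tag per strand; confirmed unidirectional: ≥ 2 sense and 0 antisense;
promoters with no tags are excluded from divergence statistics; Fisher's
exact test contrasts NBiPs against the UniP+KBiP background.

## Promoter features

Features are computed over the promoter window: GC over called bases;
per-base means of Regulatory Potential, phastCons, H3K4me3 and methylation
with validity requiring > 80 % covered bases; shape_s is the fraction of
H3K4me3 signal on the upstream half of the window, split at the window
midpoint (which is the TSS for unidirectional promoters and the promoter
centre for bidirectional ones) and oriented by the anchor gene's strand, so
mirroring a promoter leaves shape_s unchanged. Sequence features are
compared across classes with two-sided KS tests, chromatin features with
Mann–Whitney rank-sum tests — the methods language of "signed-rank" for
unpaired class comparisons is read as rank-sum, which is the coherent
unpaired test. Input-control normalisation is a separate run of the same
operations on the input track, not a subtraction, because the comparison of
interest is between profiles.

Neuron specificity of a gene set is the N/non-N flag ratio against 1,000
random same-size draws from the flagged universe (empirical p as above; an
all-N set falls back to the N count as the statistic). Ortholog cell-type
enrichment is a plain Fisher's exact test over a pre-mapped gene/cell-type
table.

## TFBS scanning and enrichment

MATCH-style scoring: counts are column-normalised to frequencies, a 0.01
per-cell pseudocount is added (frequency-first so that scaling a column is
exactly neutral), I(p) = Σ_b f ln(4f) in natural log, score
Σ_p I(p) f(p, b_p), min–max normalised with per-column extremal
frequencies; the core is the 5 consecutive highest-information positions.
Default cutoffs core 0.95 / matrix 0.90 approximate a stringent
minimum-false-positive profile and are overridable per matrix via a
TRANSFAC-style `.prf` file. Both strands are scanned; windows containing N
are skipped; a uniform (zero-information) matrix is rejected.

Enrichment builds one 2×2 table per matrix (promoters with ≥ 1 hit, NBiP vs
KBiP), two-sided Fisher p, BH across matrices, enriched iff q < 0.05 and
sample odds ratio > 1.3 (symmetric rule for KBiP-side enrichment; zero
cells leave the exact test defined and the odds ratio ±∞/NaN without
continuity correction). Positional densities use hit-start counts per
position ("density" counts hits, not hit-covered bases); the null band is
the 2.5/97.5 percentile envelope over dinucleotide-shuffled sequence sets
(Euler-path construction preserving the exact dinucleotide multiset and the
terminal nucleotides), and the central-peak flag fires when the observed
density exceeds the upper band within the central fifth of the window.
TF–target support is the mean Pearson r between a TF's expression and its
predicted targets against random same-size target draws.

## Expression dynamics

Ages transform as log2(days + 1) — the 2-day–98-year design spans four
orders of magnitude — and expression as log2(RPKM + 0.1) everywhere
(regression, clustering, correlations). The age test fits polynomials with
degree selected upward while the incremental F-test against the previous
degree has p < 0.05 (capped at 3), then tests the selected model against
the intercept-only model; `perm_p` counts age-label permutations with a
parametric p at least as small, and the FDR at the p < 0.01 cutoff is the
mean permuted positive count over the observed positive count. Fits are
vectorised across transcripts via shared QR projections, so 1,000
permutations over hundreds of transcripts take seconds. K-means (k = 12,
fixed seed, 10 restarts) clusters standardized trajectories of significant
transcripts, with per-cluster Fisher enrichment of novel transcripts and
Bonferroni correction across clusters.

Tissue specificity is a configurable stand-in rule (the study's exact
supplementary rule is not published in the main text, and output metadata
labels it as such): expressed means > 0.1 RPKM; *specific* = one expressing
tissue or top-tissue share ≥ 0.75; *ubiquitous* = expressed in ≥ 80 % of
tissues with top share ≤ 4/T; *selective* otherwise. Localization is
log2((cytosol + 0.01)/(nucleus + 0.01)). Strandedness QC reports per-sample
sense fractions and cross-strand correlations of per-gene log counts,
assuming counts come from non-overlapping gene regions.

## Synthetic data

The generator lays features out in 16-kb slots on two chromosomes
(≈ 5.3 Mb total by default), one planted configuration per slot, and draws
everything from one seeded generator (byte-identical reruns). Defaults: 50
UniP, 40 NBiP (TSS gaps half below 1 kb for the window sensitivity
analysis), 25 pc + 15 lnc KBiP, 25 + 25 overlapping tail-to-tail /
head-to-head pairs (which structurally classify as UniP / pcKBiP
promoters and are planted accordingly), 40 distal lncRNA fragments, 30 UTR
extensions, 40 splice-novelty genes, 12 junction-linked antisense
extensions, 30 context clusters; 14 samples aged 2 days–98 years
(log-spaced).

Pair correlation is injected through a shared latent trajectory: members are
√r·z + √(1−r)·ε in log space, giving expected Pearson r between members.
Half the NBiP pairs share one global trajectory that also drives a planted
TF gene, supplying the TF–target correlation signal. CAGE divergence rates:
0.95 (NBiP), 0.6 (KBiP), 0 (UniP). Track plantings: H3K4me3 Gaussian bumps
(σ = 500 nt) with amplitudes 10/7/4 for NBiP/KBiP/UniP and a downstream
shift of 600·asymmetry nt at UniPs (120 nt at NBiPs); methylation means
0.2/0.5/0.8 (reversed ordering); phastCons 0.7/0.5/0.3; RP 2.0/1.2/0.5;
promoter GC 0.62/0.55/0.45 over a 0.45-GC background. The planted motif is
a random 12-mer consensus inserted in 80 % of NBiP windows within ±150 nt of
the centre with 0.1 per-position mutation probability — detectable but not
degenerate — alongside nine decoy matrices never planted. Canonical GT–AG
dinucleotides are written at every annotated and planted splice boundary.

What the generator does **not** emulate: read-level noise and coverage
bias, assembly fragmentation, repeat content, GC-dependent mappability,
overlapping gene dense loci, and realistic CAGE tag-count distributions.
Passing tests therefore demonstrate correctness of the rules and statistics
under planted structure, not performance on real tissue data.

## Problem sizes and determinism

Test and acceptance runs use the default fixture (≈ 330 genes/clusters
slots, 14 samples) with permutation counts of 100–1,000 per stage; the
motif-enrichment repeatability check uses a trimmed layout keeping the full
40 + 40 NBiP/KBiP windows, since only those enter the enrichment table.
All stage randomness derives from a master seed via
SHA-256(seed, stage-name) so adding a stage never perturbs earlier stages;
reruns with one manifest are byte-identical.

## Known limitations

- Known/novel status is gene-span-level; exon-level classification would
  reclassify some intronic clusters.
- The cutoff-estimation null places clusters uniformly in intergenic space
  and ignores mappability/assembly gaps.
- MATCH cutoff defaults stand in for proprietary per-matrix profiles;
  enrichment conclusions are robust to them only for sharp matrices.
- The tissue-specificity rule is a documented stand-in (see above).
- Expression of a cluster is the mean over member contig rows; no
  isoform-level quantification is attempted.
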