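# nbipscan

Discovery of **novel bidirectional promoters (NBiPs)** — head-to-head pairs
of an annotated gene and a novel antisense lncRNA — from strand-specific
RNA-seq transcript contigs, together with the surrounding analyses such a
study needs: known/novel transcript classification, novel elements of
annotated genes, sense/antisense pair correlation, CAGE-based divergent
transcription evidence, promoter sequence/epigenetic feature contrasts,
TFBS enrichment, and developmental expression dynamics.

## Who this is for

Transcriptomics groups working with assembled contigs from stranded RNA-seq
of a tissue time course (the motivating setting is postnatal human
prefrontal cortex development), who want to classify the unannotated
fraction of the transcriptome and ask whether novel upstream-antisense
lncRNAs mark a distinct promoter class.

## The model in brief

- **Clusters.** Mapped contigs overlapping by ≥ 1 nt on the same strand
  merge transitively into clusters; a cluster overlapping an annotated gene
  span (same strand, ≥ 1 nt) is *known*, otherwise *novel*.
- **Promoter classes.** For a gene with TSS *t*: **NBiP** if a novel cluster
  lies head-to-head with |t − t′| ≤ 2 kb (t′ the cluster 5′ end); **pcKBiP
  / lncKBiP** if the partner is an annotated protein-coding / lncRNA gene;
  **UniP** if no transcript or cluster lies within 5 kb upstream. KBiP takes
  precedence over NBiP.
- **Divergence.** CAGE tags are summed per strand over the promoter window
  (2 kb centred between the paired TSSs). *Divergent*: ≥ 1 tag on each
  strand; *confirmed unidirectional*: ≥ 2 sense, 0 antisense. Fisher's exact
  test contrasts the divergent fraction at NBiPs against UniP+KBiP.
- **Features.** GC, Regulatory Potential, phastCons, H3K4me3 density and
  shape s = (upstream signal)/(total signal), methylation; KS tests for
  sequence features, rank-sum for chromatin; features need > 80 % window
  coverage.
- **TFBS.** MATCH-style scanning: with column frequencies f(p,b)
  (pseudocount 0.01) and information I(p) = Σ_b f ln 4f, score = Σ_p
  I(p)·f(p,b_p), min–max normalised to mss ∈ [0,1] (css over the 5-position
  core); enrichment per matrix is Fisher + BH with an odds-ratio > 1.3
  filter, and positional nulls come from Altschul–Erickson dinucleotide
  shuffles.
- **Dynamics.** Polynomial regression of log2(RPKM+0.1) on log2(age+1)
  (degree ≤ 3 by incremental F-tests), permutation-calibrated p-values and
  FDR, K-means (k = 12) trajectory clustering with per-cluster Fisher
  enrichment of novel transcripts.

A synthetic-data generator (`nbipscan.simulate`) emits a complete,
internally consistent toy dataset — genome FASTA, GTF, BED12 contigs, CAGE
BED, bedGraph tracks, TRANSFAC matrices, expression tables — with every
planted element recorded in truth tables, so the whole pipeline is testable
without downloads.

## Worked example

```python
from nbipscan import (SimConfig, simulate, merge_contigs, annotate_status,
                      call_promoters, divergence_enrichment)
from nbipscan import io as nio

paths = simulate(SimConfig(rng_seed=1), "sim")
genes = nio.read_annotation(paths["gtf"])
clusters = annotate_status(merge_contigs(nio.read_bed12(paths["contigs"])), genes)
calls = call_promoters(genes, clusters, nio.read_cage(paths["cage"]))
enr = divergence_enrichment(calls)
print(sum(c.klass == "NBiP" for c in calls), enr.odds_ratio, enr.p)
```

prints

```
40 49.333333333333336 6.672530321862751e-18
```

i.e. all 40 planted novel bidirectional promoters are recovered, and
divergent CAGE evidence (37/40 NBiPs vs 33/165 background promoters) is
enriched at them with odds ratio ≈ 49 at p ≈ 7·10⁻¹⁸. The scripts under
`examples/` walk through each capability the same way (transcript
classification, promoter features, TFBS enrichment, expression dynamics)
and print a line explaining each number.

The command line mirrors the library:

```bash
nbipscan simulate --outdir sim --seed 1
nbipscan all --fasta sim/genome.fa --gtf sim/annotation.gtf \
    --contigs sim/contigs.bed12 --expr sim/expression.tsv \
    --cage sim/cage.bed --outdir run
```

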