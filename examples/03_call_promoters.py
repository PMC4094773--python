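"""Classify novel clusters by genomic context and type promoters.

Intergenic novel clusters within 4 kb of a gene fall into four categories
(upstream/downstream x sense/antisense). Promoters are typed UniP / pcKBiP /
lncKBiP / NBiP, and CAGE tags aggregated over each promoter window provide
divergence evidence: the central question is whether NBiPs show divergent
transcription (>= 1 tag on each strand) more often than UniP+KBiP promoters.
"""

from collections import Counter

from _shared import dataset
from nbipscan import (
    annotate_status,
    call_promoters,
    classify_context,
    divergence_enrichment,
    merge_contigs,
)
from nbipscan import io as nio

sim = dataset()
genes = nio.read_annotation(sim / "annotation.gtf")
clusters = annotate_status(merge_contigs(nio.read_bed12(sim / "contigs.bed12")), genes)

context = classify_context(clusters, genes, cutoff=4000)
print("genomic context of near-gene novel clusters (<= 4 kb):")
for cat, n in sorted(Counter(c.category for c in context).items()):
    print(f"  {cat:22s} {n:4d}")

cage = nio.read_cage(sim / "cage.bed")
calls = call_promoters(genes, clusters, cage, bidir_window=2000, unip_window=5000)
print("\npromoter classes:")
for k, n in sorted(Counter(c.klass for c in calls).items()):
    print(f"  {k:8s} {n:4d}")

enr = divergence_enrichment(calls)
print(f"\ndivergent CAGE signature at NBiPs: {enr.a}/{enr.a + enr.b} "
      f"vs background {enr.c}/{enr.c + enr.d}")
print(f"Fisher's exact test: OR = {enr.odds_ratio:.1f}, p = {enr.p:.2e}")
print("A large odds ratio means bidirectional CAGE evidence concentrates at")
print("the novel head-to-head gene/lncRNA promoters, as planted.")
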