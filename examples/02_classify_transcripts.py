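"""Merge mapped contigs, split known from novel, and call novel elements.

Contigs overlapping on the same strand merge into clusters; a cluster
touching an annotated gene span (same strand, >= 1 nt) is "known", the rest
are candidate novel transcripts. Known clusters are then scanned for novel
internal exons, splice-site variants and UTR extensions (>= 100 nt), each
validated against an alternate assembly, H3K4me3 peaks and polyA sites.
"""

from collections import Counter

import pyfaidx

from _shared import dataset
from nbipscan import annotate_status, call_novel_elements, merge_contigs, validate_elements
from nbipscan import io as nio

sim = dataset()
genes = nio.read_annotation(sim / "annotation.gtf")
clusters = annotate_status(merge_contigs(nio.read_bed12(sim / "contigs.bed12")), genes)
n_known = sum(c.status == "known" for c in clusters)
print(f"{len(clusters)} contig clusters: {n_known} known, "
      f"{len(clusters) - n_known} novel")

genome = pyfaidx.Fasta(str(sim / "genome.fa"))
calls = call_novel_elements(clusters, genes, genome)
alt = annotate_status(merge_contigs(nio.read_bed12(sim / "alt_contigs.bed12")), genes)
peaks = [iv for iv, _, _ in nio.read_bed6(sim / "h3k4me3_peaks.bed")]
polya = [iv for iv, _, _ in nio.read_bed6(sim / "polya_sites.bed")]
validate_elements(calls, alt, peaks, polya)

print("\nnovel elements of annotated genes:")
for kind, n in sorted(Counter(c.element_kind for c in calls).items()):
    v = sum(any(c.validated.values()) for c in calls if c.element_kind == kind)
    print(f"  {kind:20s} {n:4d} called, {v:4d} with independent support")
print("\nA validated utr5_extension, for instance, extends an annotated 5'")
print("end by >= 100 nt and has an H3K4me3 peak within 2 kb of the new TSS.")
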