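"""Contig merging and known/novel status assignment.

Mapped transcript contigs whose spans overlap by at least one nucleotide on
the same chromosome and strand are merged transitively into contig clusters.
A cluster is "known" when its span overlaps an annotated gene span on the
same strand by at least one nucleotide, otherwise "novel".
"""

from __future__ import annotations

import numpy as np

from .intervals import ContigCluster, GeneModel, GenomicInterval
from .io import Contig


def _merge_blocks(blocks: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of blocks, merging any that overlap by >= 1 nt."""
    blocks = sorted(blocks, key=lambda b: (b.start, b.end))
    out: list[GenomicInterval] = []
    for b in blocks:
        if out and b.start < out[-1].end:
            if b.end > out[-1].end:
                prev = out[-1]
                out[-1] = GenomicInterval(prev.chrom, prev.start, b.end, prev.strand)
        else:
            out.append(GenomicInterval(b.chrom, b.start, b.end, b.strand))
    return out


def merge_contigs(contigs: list[Contig]) -> list[ContigCluster]:
    """Transitively merge same-strand, same-chromosome overlapping contigs.

    The result is independent of input order: clusters are rebuilt by a sweep
    over (chrom, strand, start)-sorted spans, and cluster ids are assigned in
    genomic order.
    """
    groups: dict[tuple[str, str], list[Contig]] = {}
    for c in contigs:
        groups.setdefault((c.span.chrom, c.strand), []).append(c)

    clusters: list[ContigCluster] = []
    for (chrom, strand), members in sorted(groups.items()):
        members.sort(key=lambda c: (c.span.start, c.span.end, c.name))
        open_members: list[Contig] = []
        span_end = -1
        for c in members + [None]:  # type: ignore[list-item]
            if c is not None and open_members and c.span.start < span_end:
                open_members.append(c)
                span_end = max(span_end, c.span.end)
                continue
            if open_members:
                start = min(m.span.start for m in open_members)
                end = max(m.span.end for m in open_members)
                blocks = _merge_blocks([b for m in open_members for b in m.blocks])
                clusters.append(
                    ContigCluster(
                        cluster_id="",
                        span=GenomicInterval(chrom, start, end, strand),
                        strand=strand,
                        exon_blocks=blocks,
                        members=sorted(m.name for m in open_members),
                    )
                )
            if c is not None:
                open_members = [c]
                span_end = c.span.end
    clusters.sort(key=lambda cl: (cl.chrom, cl.span.start, cl.span.end, cl.strand))
    for i, cl in enumerate(clusters, start=1):
        cl.cluster_id = f"CL{i:06d}"
    return clusters


def annotate_status(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    seqdict: set[str] | None = None,
) -> list[ContigCluster]:
    """Set ``status`` to known/novel by same-strand gene-span overlap.

    A single nucleotide of overlap with any annotated gene span on the same
    strand makes a cluster "known". The check is span-level (the annotated
    spans already merge all transcripts of a gene).
    """
    if seqdict is not None:
        missing = {c.chrom for c in clusters} | {g.chrom for g in genes}
        missing -= seqdict
        if missing:
            raise ValueError(f"chromosomes absent from sequence dictionary: {sorted(missing)}")

    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key in {(g.chrom, g.strand) for g in genes}:
        spans = sorted(
            (g.span.start, g.span.end) for g in genes if (g.chrom, g.strand) == key
        )
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        ends = np.array([e for _, e in spans], dtype=np.int64)
        # running max of ends lets a binary search bound the overlap scan
        by_key[key] = (starts, np.maximum.accumulate(ends))

    for cl in clusters:
        key = (cl.chrom, cl.strand)
        cl.status = "novel"
        if key in by_key:
            starts, max_ends = by_key[key]
            i = int(np.searchsorted(starts, cl.span.end, side="left"))
            if i > 0 and max_ends[i - 1] > cl.span.start:
                cl.status = "known"
    return clusters
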