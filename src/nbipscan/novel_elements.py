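"""Novel elements of annotated genes: internal exons, splice variants, UTR extensions.

A "known" contig cluster contributes novel elements to an annotated
transcript when it shares at least one exon (exact boundary match of a
block) and additionally carries sequence the annotation lacks:

* ``novel_internal_exon`` — an extra block fully inside an intron of the
  shared transcript;
* ``novel_donor`` / ``novel_acceptor`` — a block sharing exactly one boundary
  with an annotated internal exon, the novel boundary lying outside the exon
  and flanked by the canonical GT (donor) / AG (acceptor) dinucleotide in
  transcript orientation;
* ``utr5_extension`` / ``utr3_extension`` — the cluster span extends past the
  annotated 5'/3' terminus by at least ``min_utr_ext`` nt (default 100).

Validation attaches independent evidence: reproduction by an alternate
cluster set, an H3K4me3 peak within 2 kb of a novel 5' end, or a polyA site
within 2 kb of a novel 3' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import ContigCluster, GeneModel, GenomicInterval

log = logging.getLogger(__name__)

DEFAULT_MIN_UTR_EXT = 100
VALIDATION_WINDOW = 2000


@dataclass
class NovelElementCall:
    gene_id: str
    element_kind: str
    interval: GenomicInterval
    supporting_cluster_id: str
    validated: dict = field(
        default_factory=lambda: {"alt_assembler": False, "h3k4me3_peak": False, "polya": False}
    )


def _fetch(genome, chrom: str, start: int, end: int) -> str | None:
    """Uppercase genomic sequence; None if off the chromosome end."""
    if start < 0:
        return None
    try:
        seq = genome[chrom][start:end].seq  # pyfaidx FastaRecord
    except (KeyError, IndexError):
        return None
    if len(seq) != end - start:
        return None
    return seq.upper()


def _donor_ok(genome, chrom, boundary, strand) -> bool | None:
    """Canonical GT immediately intronward of a donor boundary."""
    if strand == "+":
        s = _fetch(genome, chrom, boundary, boundary + 2)
        want = "GT"
    else:
        s = _fetch(genome, chrom, boundary - 2, boundary)
        want = "AC"  # revcomp(GT)
    return None if s is None else s == want


def _acceptor_ok(genome, chrom, boundary, strand) -> bool | None:
    """Canonical AG immediately intronward of an acceptor boundary."""
    if strand == "+":
        s = _fetch(genome, chrom, boundary - 2, boundary)
        want = "AG"
    else:
        s = _fetch(genome, chrom, boundary, boundary + 2)
        want = "CT"  # revcomp(AG)
    return None if s is None else s == want


def call_novel_elements(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    genome,
    min_utr_ext: int = DEFAULT_MIN_UTR_EXT,
) -> list[NovelElementCall]:
    """Scan known clusters against annotated transcripts for novel elements."""
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    calls: dict[tuple, NovelElementCall] = {}

    def add(gene_id, kind, iv, cid):
        key = (gene_id, kind, iv.start, iv.end)
        calls.setdefault(key, NovelElementCall(gene_id, kind, iv, cid))

    for cl in clusters:
        if cl.status != "known":
            continue
        for g in by_key.get((cl.chrom, cl.strand), []):
            if not g.span.overlaps(cl.span):
                continue
            for tx in g.transcripts:
                exact = {(e.start, e.end) for e in tx}
                shares_exon = any((b.start, b.end) in exact for b in cl.exon_blocks)
                introns = [
                    (a.end, b.start) for a, b in zip(tx, tx[1:]) if a.end < b.start
                ]
                internal = tx[1:-1] if len(tx) > 2 else []
                tx_start, tx_end = tx[0].start, tx[-1].end

                if shares_exon:
                    for b in cl.exon_blocks:
                        if (b.start, b.end) in exact:
                            continue
                        if any(s <= b.start and b.end <= e for s, e in introns):
                            add(g.gene_id, "novel_internal_exon", b, cl.cluster_id)
                    # UTR extensions measured on the cluster span
                    left = tx_start - cl.span.start
                    right = cl.span.end - tx_end
                    if left >= min_utr_ext:
                        iv = GenomicInterval(cl.chrom, cl.span.start, tx_start, cl.strand)
                        kind = "utr5_extension" if g.strand == "+" else "utr3_extension"
                        add(g.gene_id, kind, iv, cl.cluster_id)
                    if right >= min_utr_ext:
                        iv = GenomicInterval(cl.chrom, tx_end, cl.span.end, cl.strand)
                        kind = "utr3_extension" if g.strand == "+" else "utr5_extension"
                        add(g.gene_id, kind, iv, cl.cluster_id)

                for b in cl.exon_blocks:
                    for e in internal:
                        share_start = b.start == e.start and b.end != e.end
                        share_end = b.end == e.end and b.start != e.start
                        if share_start and b.end > e.end:
                            # novel boundary beyond the exon's genomic end
                            kind = "novel_donor" if g.strand == "+" else "novel_acceptor"
                            ok = (_donor_ok if kind == "novel_donor" else _acceptor_ok)(
                                genome, cl.chrom, b.end, g.strand)
                            if ok is None:
                                log.warning(
                                    "splice-signal lookup off chromosome end at %s:%d; call dropped",
                                    cl.chrom, b.end)
                            elif ok:
                                add(g.gene_id, kind, b, cl.cluster_id)
                        elif share_end and b.start < e.start:
                            kind = "novel_acceptor" if g.strand == "+" else "novel_donor"
                            ok = (_acceptor_ok if kind == "novel_acceptor" else _donor_ok)(
                                genome, cl.chrom, b.start, g.strand)
                            if ok is None:
                                log.warning(
                                    "splice-signal lookup off chromosome end at %s:%d; call dropped",
                                    cl.chrom, b.start)
                            elif ok:
                                add(g.gene_id, kind, b, cl.cluster_id)

    out = sorted(
        calls.values(),
        key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end,
                       c.element_kind, c.gene_id),
    )
    return out


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_len(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def validate_elements(
    calls: list[NovelElementCall],
    alt_clusters: list[ContigCluster] | None = None,
    h3k4me3_peaks: list[GenomicInterval] | None = None,
    polya_sites: list[GenomicInterval] | None = None,
    window: int = VALIDATION_WINDOW,
) -> list[NovelElementCall]:
    """Attach alt-assembly / H3K4me3-peak / polyA validation flags in place."""
    alt_clusters = alt_clusters or []
    h3k4me3_peaks = h3k4me3_peaks or []
    polya_sites = polya_sites or []

    alt_blocks: dict[tuple[str, str], set[tuple[int, int]]] = {}
    alt_spans: dict[tuple[str, str], list[GenomicInterval]] = {}
    for cl in alt_clusters:
        key = (cl.chrom, cl.strand)
        alt_blocks.setdefault(key, set()).update(
            (b.start, b.end) for b in cl.exon_blocks)
        alt_spans.setdefault(key, []).append(cl.span)

    def point_near(pos: int, chrom: str, ivs: list[GenomicInterval]) -> bool:
        for iv in ivs:
            if iv.chrom != chrom:
                continue
            d = 0 if iv.contains_point(pos) else min(
                abs(pos - iv.start), abs(pos - (iv.end - 1)))
            if d <= window:
                return True
        return False

    for call in calls:
        key = (call.interval.chrom, call.interval.strand)
        if call.element_kind in ("novel_internal_exon", "novel_donor", "novel_acceptor"):
            call.validated["alt_assembler"] = (
                (call.interval.start, call.interval.end) in alt_blocks.get(key, set()))
        else:
            call.validated["alt_assembler"] = any(
                _reciprocal_overlap(call.interval, s) >= 0.5
                for s in alt_spans.get(key, []))
        if call.element_kind == "utr5_extension":
            novel5 = (call.interval.start if call.interval.strand == "+"
                      else call.interval.end - 1)
            call.validated["h3k4me3_peak"] = point_near(
                novel5, call.interval.chrom, h3k4me3_peaks)
        if call.element_kind == "utr3_extension":
            novel3 = (call.interval.end - 1 if call.interval.strand == "+"
                      else call.interval.start)
            call.validated["polya"] = point_near(
                novel3, call.interval.chrom, polya_sites)
    return calls
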