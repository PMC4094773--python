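"""Streaming readers and writers for GTF, BED6/BED12, bedGraph and FASTA.

GTF is the Ensembl dialect (1-based inclusive coordinates, ``gene_id`` /
``transcript_id`` / ``gene_biotype`` attributes); internally everything is
0-based half-open. Writers emit records in deterministic (chrom, start)
order so that repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .intervals import (
    CageTags,
    ContigCluster,
    GeneModel,
    GenomicInterval,
    SignalTrack,
    classify_biotype,
)

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _norm_chrom(name: str, chr_mode: str) -> str:
    if chr_mode == "strip":
        return name[3:] if name.startswith("chr") else name
    if chr_mode == "add":
        return name if name.startswith("chr") else "chr" + name
    return name


# ---------------------------------------------------------------------------
# GTF

def read_annotation(path, chr_mode: str = "keep") -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into GeneModels (exon features only)."""
    genes: dict[str, dict] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: unknown strand symbol {strand!r} on line {lineno}")
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad coordinates") from exc
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad coordinates")
            attr = dict(_ATTR_RE.findall(attrs))
            try:
                gid = attr["gene_id"]
                tid = attr["transcript_id"]
            except KeyError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: missing {exc.args[0]}"
                ) from exc
            rec = genes.setdefault(
                gid,
                {"strand": strand, "biotype": attr.get("gene_biotype", "other"), "tx": {}},
            )
            rec["tx"].setdefault(tid, []).append(
                GenomicInterval(_norm_chrom(chrom, chr_mode), start0, end0, strand)
            )
    if not genes:
        log.warning("%s: no exon records found, returning empty annotation", path)
        return []
    out = []
    for gid in sorted(genes):
        rec = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                biotype=classify_biotype(rec["biotype"]),
                strand=rec["strand"],
                transcripts=[rec["tx"][tid] for tid in sorted(rec["tx"])],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return out


def write_annotation(genes: list[GeneModel], path, source: str = "nbipscan") -> None:
    rows = []
    for g in genes:
        for ti, tx in enumerate(g.transcripts):
            tid = f"{g.gene_id}.t{ti + 1}"
            for e in tx:
                rows.append((e.chrom, e.start, e.end, g.strand, g.gene_id, tid, g.biotype))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, strand, gid, tid, biotype in rows:
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; gene_biotype "{biotype}";'
            )
            fh.write(
                f"{chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED

@dataclass
class Contig:
    """A single mapped transcript contig (one BED12 record)."""

    name: str
    span: GenomicInterval
    strand: str
    blocks: list[GenomicInterval]


def read_bed12(path, chr_mode: str = "keep") -> list[Contig]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected BED12 (12 fields)")
            chrom = _norm_chrom(f[0], chr_mode)
            start, end = int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            blocks = []
            for off, size in zip(offsets, sizes):
                b = GenomicInterval(chrom, start + off, start + off + size, strand)
                if b.end > end:
                    raise ValueError(f"{path}: line {lineno}: block outside span")
                blocks.append(b)
            out.append(
                Contig(name=name, span=GenomicInterval(chrom, start, end, strand), strand=strand, blocks=blocks)
            )
    return out


def write_bed12(records, path) -> None:
    """Write Contigs or ContigClusters as BED12, sorted by (chrom, start)."""
    rows = []
    for r in records:
        name = getattr(r, "cluster_id", None) or getattr(r, "name")
        blocks = sorted(getattr(r, "exon_blocks", None) or r.blocks,
                        key=lambda b: b.start)
        span = r.span
        sizes = ",".join(str(len(b)) for b in blocks)
        offs = ",".join(str(b.start - span.start) for b in blocks)
        rows.append(
            (span.chrom, span.start, span.end, name, r.strand, len(blocks), sizes, offs)
        )
    rows.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, strand, nb, sizes, offs in rows:
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t{nb}\t{sizes}\t{offs}\n"
            )


def read_bed6(path, chr_mode: str = "keep") -> list[tuple[GenomicInterval, str, float]]:
    """Read BED3-6 into (interval, name, score) records."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            chrom = _norm_chrom(f[0], chr_mode)
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append((GenomicInterval(chrom, int(f[1]), int(f[2]), strand), name, score))
    return out


def write_bed6(records, path) -> None:
    """records: iterable of (interval, name, score)."""
    rows = sorted(
        (iv.chrom, iv.start, iv.end, name, score, iv.strand) for iv, name, score in records
    )
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            score_s = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score_s}\t{strand}\n")


def read_cage(path, chr_mode: str = "keep") -> CageTags:
    """CAGE tags as BED6: 1-nt intervals, score column = tag count."""
    recs = []
    for iv, _name, score in read_bed6(path, chr_mode):
        if len(iv) != 1:
            raise ValueError(f"{path}: CAGE tag intervals must be 1 nt")
        recs.append((iv.chrom, iv.start, iv.strand, int(score)))
    return CageTags.from_records(recs)


def write_cage(tags: CageTags, path) -> None:
    write_bed6(
        (
            (GenomicInterval(chrom, pos, pos + 1, strand), "tag", count)
            for chrom, pos, strand, count in tags.records()
        ),
        path,
    )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, kind: str = "signal", chr_mode: str = "keep") -> SignalTrack:
    track = SignalTrack(kind=kind)
    chroms: dict[str, list[list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 bedGraph fields")
            chrom = _norm_chrom(f[0], chr_mode)
            rec = chroms.setdefault(chrom, [[], [], []])
            rec[0].append(int(f[1]))
            rec[1].append(int(f[2]))
            rec[2].append(float(f[3]))
    for chrom, (s, e, v) in chroms.items():
        track.add_segments(chrom, s, e, v)
    return track.finalize()


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.segments(chrom)
            for start, end, val in zip(s, e, v):
                fh.write(f"{chrom}\t{start}\t{end}\t{val:g}\n")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# junctions

def read_junctions(path, chr_mode: str = "keep") -> list[tuple[str, int, int, str]]:
    """Splice junctions as TSV/BED: chrom, intron start, intron end, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: expected chrom/start/end/strand")
            strand = f[5] if len(f) > 5 else f[3]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            out.append((_norm_chrom(f[0], chr_mode), int(f[1]), int(f[2]), strand))
    return out


def write_junctions(junctions, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, strand in sorted(junctions):
            fh.write(f"{chrom}\t{start}\t{end}\t{strand}\n")
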