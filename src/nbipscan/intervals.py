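"""Genomic data model: intervals, gene models, contig clusters, signal tracks.

All coordinates are 0-based half-open throughout the package. Format readers
and writers (:mod:`nbipscan.io`) convert at the boundary where a format uses a
different convention (GTF is 1-based inclusive; BED and bedGraph are native).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

#: gene_biotype values collapsed onto the five biotypes the pipeline uses
BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "processed_transcript": "processed_transcript",
}


def classify_biotype(raw: str) -> str:
    if raw in BIOTYPE_MAP:
        return BIOTYPE_MAP[raw]
    if "pseudogene" in raw:
        return "pseudogene"
    return "other"


@dataclass
class GenomicInterval:
    """Half-open genomic interval with strand.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``strand`` is
    one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True if the two intervals share >= 1 nt (optionally same strand)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in nt between the two spans (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("gap between different chromosomes is undefined")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(other.start - self.end, self.start - other.end)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """Annotated gene: one or more exon chains sharing a strand and a span."""

    gene_id: str
    biotype: str
    strand: str
    transcripts: list[list[GenomicInterval]]
    span: GenomicInterval = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.transcripts or any(len(t) == 0 for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: needs >= 1 exon per transcript")
        for tx in self.transcripts:
            tx.sort(key=lambda e: e.start)
        chrom = self.transcripts[0][0].chrom
        lo = min(e.start for tx in self.transcripts for e in tx)
        hi = max(e.end for tx in self.transcripts for e in tx)
        if self.span is None:
            self.span = GenomicInterval(chrom, lo, hi, self.strand)
        else:
            if not (self.span.start <= lo and hi <= self.span.end):
                raise ValueError(f"gene {self.gene_id}: exon outside span")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def tss(self) -> int:
        """Transcription start site (5' boundary in genome coordinates)."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def tts(self) -> int:
        return self.span.end if self.strand == "+" else self.span.start


@dataclass
class ContigCluster:
    """Merged mapped-contig cluster with exon blocks and novelty status."""

    cluster_id: str
    span: GenomicInterval
    strand: str
    exon_blocks: list[GenomicInterval]
    status: str | None = None  # "known" | "novel"
    mean_rpkm: float | None = None
    context: str | None = None
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exon_blocks.sort(key=lambda b: b.start)
        for b in self.exon_blocks:
            if b.start < self.span.start or b.end > self.span.end:
                raise ValueError(
                    f"cluster {self.cluster_id}: block outside span"
                )
        for a, b in zip(self.exon_blocks, self.exon_blocks[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"cluster {self.cluster_id}: overlapping exon blocks"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def five_prime(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def three_prime(self) -> int:
        return self.span.end if self.strand == "+" else self.span.start


class SignalTrack:
    """Piecewise-constant genomic signal (bedGraph-like).

    Segments are stored per chromosome as sorted, non-overlapping
    ``(start, end, value)`` arrays; ``kind`` names what the track measures
    (h3k4me3, input, methylation, phastcons, rp_score).
    """

    def __init__(self, kind: str = "signal"):
        self.kind = kind
        self._chroms: dict[str, list[np.ndarray]] = {}
        self._final = True

    def add_segments(self, chrom, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("signal values must be finite")
        if np.any(ends <= starts):
            raise ValueError("signal segments must have end > start")
        cur = self._chroms.setdefault(chrom, [np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)])
        cur[0] = np.concatenate([cur[0], starts])
        cur[1] = np.concatenate([cur[1], ends])
        cur[2] = np.concatenate([cur[2], values])
        self._final = False

    def finalize(self) -> "SignalTrack":
        for chrom, (s, e, v) in self._chroms.items():
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._chroms[chrom] = [s, e, v]
        self._final = True
        return self

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def segments(self, chrom: str):
        s, e, v = self._chroms.get(chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0),))
        return s, e, v

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-nucleotide values over [start, end); NaN where uncovered."""
        if not self._final:
            self.finalize()
        out = np.full(end - start, np.nan)
        if chrom not in self._chroms:
            return out
        s, e, v = self._chroms[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start)
            b = min(int(e[i]), end)
            if a < b:
                out[a - start : b - start] = v[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """(mean over covered bases, covered fraction) for the window."""
        vals = self.per_base(chrom, start, end)
        ok = np.isfinite(vals)
        frac = float(ok.mean()) if len(vals) else 0.0
        mean = float(vals[ok].mean()) if ok.any() else float("nan")
        return mean, frac


class CageTags:
    """Stranded 1-nt CAGE tag positions with integer counts."""

    def __init__(self):
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_records(cls, records) -> "CageTags":
        """records: iterable of (chrom, pos, strand, count)."""
        buf: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, pos, strand, count in records:
            count = int(count)
            if count < 1:
                raise ValueError(f"CAGE tag count must be >= 1 (got {count})")
            if strand not in ("+", "-"):
                raise ValueError(f"CAGE tags must be stranded (got {strand!r})")
            buf.setdefault((chrom, strand), []).append((int(pos), count))
        obj = cls()
        for key, rows in buf.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            cnt = np.array([r[1] for r in rows], dtype=np.int64)
            obj._data[key] = (pos, cnt)
        return obj

    def count(self, chrom: str, start: int, end: int, strand: str) -> int:
        """Total tag count on one strand within [start, end)."""
        key = (chrom, strand)
        if key not in self._data:
            return 0
        pos, cnt = self._data[key]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return int(cnt[lo:hi].sum())

    def records(self):
        for (chrom, strand), (pos, cnt) in sorted(self._data.items()):
            for p, c in zip(pos, cnt):
                yield chrom, int(p), strand, int(c)

    def __len__(self) -> int:
        return sum(len(p) for p, _ in self._data.values())
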