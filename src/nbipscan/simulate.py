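"""Synthetic prefrontal-cortex-like dataset with planted, recoverable structure.

The generator lays a toy two-chromosome genome out in fixed-width "slots",
each hosting one planted configuration: unidirectional promoters (UniP),
known bidirectional promoters (two annotated genes head-to-head; pcKBiP with
two protein-coding genes, lncKBiP with a protein-coding/lncRNA pair), novel
bidirectional promoters (NBiP: an annotated gene head-to-head with a novel
antisense transcript contig), overlapping sense/antisense gene pairs
(head-to-head and tail-to-tail), distal intergenic lncRNA fragments, novel
elements of annotated genes (UTR extensions, internal exons, splice-site
variants), splice-junction-linked antisense extensions, and near-gene
clusters for the four genomic-context categories.

Planted quantitative structure:

* expression across ``n_samples`` aged individuals (log-spaced 2 days to 98
  years) with pairwise Pearson correlation ``pair_r`` injected through a
  shared latent age trajectory plus independent noise;
* divergent CAGE tags at bidirectional promoters (>=1 tag per strand) and
  strictly unidirectional tags (>=2 sense, 0 antisense) at UniPs;
* GC content, Regulatory Potential, phastCons ordered NBiP > KBiP > UniP and
  DNA methylation reversed; H3K4me3 amplitude ordered NBiP > KBiP > UniP with
  a downstream-shifted (asymmetric) profile at UniPs only;
* a consensus transcription-factor motif inserted (with per-position mutation
  probability ``motif_mutation_p``) in a fraction of NBiP windows and nowhere
  else, written to a TRANSFAC-format matrix library together with decoys;
* canonical GT-AG dinucleotides at every annotated and planted splice
  boundary.

Every planted element is recorded in plain-text truth tables so recovery can
be scored. Output is byte-identical for a fixed ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .intervals import GenomicInterval, SignalTrack, CageTags

log = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def default_ages(n: int, lo: float = 2.0, hi: float = 98 * 365.25) -> np.ndarray:
    """Postnatal ages in days, log-spaced over the 2 d - 98 y design."""
    return np.geomspace(lo, hi, n)


@dataclass
class SimConfig:
    """Planted counts, effect sizes and noise levels for the toy dataset."""

    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    slot_size: int = 16000

    n_unip: int = 50
    n_nbip: int = 40
    n_kbip_pc: int = 25
    n_kbip_lnc: int = 15
    n_t2t: int = 25
    n_h2h: int = 25
    n_distal: int = 40
    n_utr5: int = 15
    n_utr3: int = 15
    n_internal_exon: int = 20
    n_donor: int = 10
    n_acceptor: int = 10
    n_ctx_upstream_sense: int = 10
    n_ctx_downstream_sense: int = 10
    n_ctx_downstream_antisense: int = 10
    n_junction: int = 12

    n_samples: int = 14
    age_min_days: float = 2.0
    age_max_days: float = 98 * 365.25

    pair_r: float = 0.8  # |Pearson r| planted in NBiP / SAS pairs
    ctx_r: float = 0.6  # r planted for context (near-gene) pairs
    kbip_r: float = 0.4  # r planted between KBiP gene pairs

    nbip_divergent_rate: float = 0.95
    kbip_divergent_rate: float = 0.6

    motif_insertion_rate: float = 0.8
    motif_mutation_p: float = 0.1
    n_decoy_matrices: int = 9

    h3k4me3_asymmetry: float = 1.0  # 1.0 => UniP peak shifted 600 nt downstream
    h3k4me3_amp: dict = field(
        default_factory=lambda: {"NBiP": 10.0, "KBiP": 7.0, "UniP": 4.0}
    )
    methylation_means: dict = field(
        default_factory=lambda: {"NBiP": 0.2, "KBiP": 0.5, "UniP": 0.8}
    )
    phastcons_means: dict = field(
        default_factory=lambda: {"NBiP": 0.7, "KBiP": 0.5, "UniP": 0.3}
    )
    rp_means: dict = field(
        default_factory=lambda: {"NBiP": 2.0, "KBiP": 1.2, "UniP": 0.5}
    )
    gc_content: dict = field(
        default_factory=lambda: {"NBiP": 0.62, "KBiP": 0.55, "UniP": 0.45}
    )
    background_gc: float = 0.45
    track_noise_sd: float = 0.2
    track_bin: int = 50

    expr_mu: float = 3.0
    expr_mu_sd: float = 0.7
    expr_sd: float = 0.8
    distal_trend_rate: float = 0.5
    n_tissues: int = 8
    strandedness: float = 0.95

    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name, val in dataclasses.asdict(self).items():
            if name.startswith("n_") and val < 0:
                raise ValueError(f"{name} must be >= 0")
        for r in (self.pair_r, self.ctx_r, self.kbip_r):
            if abs(r) > 1:
                raise ValueError("planted correlations must satisfy |r| <= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
        if "chrom_names" in d:
            d = dict(d, chrom_names=tuple(d["chrom_names"]))
        return cls(**d)


# Gene geometry (offsets along the gene's own orientation, nt)
GENE_LEN = 2500
EXONS = [(0, 400), (900, 1500), (2100, 2500)]
LNC_LEN = 1200
ANCHOR = 8000  # slot anchor offset


def _oiv(chrom: str, base: int, sgn: int, a: int, b: int, strand: str) -> GenomicInterval:
    """Interval from oriented offsets a < b (downstream-positive)."""
    if sgn > 0:
        return GenomicInterval(chrom, base + a, base + b, strand)
    return GenomicInterval(chrom, base - b, base - a, strand)


def _opos(base: int, sgn: int, off: int) -> int:
    return base + off if sgn > 0 else base - off - 1


class _Builder:
    """Accumulates planted elements while slots are laid out."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.gtf_rows: list[tuple] = []  # (gene_id, biotype, strand, [exon ivs])
        self.contigs: list[nio.Contig] = []
        self.alt_contigs: list[nio.Contig] = []
        self.cage: list[tuple] = []  # (chrom,pos,strand,count)
        self.track_plants: list[tuple] = []  # (chrom, center, klass, sgn)
        self.gc_windows: list[tuple] = []  # (chrom, start, end, gc)
        self.splice_introns: list[tuple] = []  # (iv, strand)
        self.motif_sites: list[tuple] = []  # (chrom, pos, strand, anchor_gene)
        self.peaks: list[GenomicInterval] = []
        self.polya: list[GenomicInterval] = []
        self.junctions: list[tuple] = []
        self.truth_promoters: list[dict] = []
        self.truth_pairs: list[dict] = []
        self.truth_context: list[dict] = []
        self.truth_elements: list[dict] = []
        self.truth_links: list[dict] = []
        self.expr_pairs: list[tuple] = []  # (id1, id2, r, program)
        self.expr_trend: list[tuple] = []  # (id, shape)
        self.tf_program_targets: list[str] = []

    # -- primitive adders ---------------------------------------------------

    def gene(self, gid, chrom, base, sgn, biotype="protein_coding", exons=EXONS):
        strand = "+" if sgn > 0 else "-"
        ivs = [_oiv(chrom, base, sgn, a, b, strand) for a, b in exons]
        self.gtf_rows.append((gid, biotype, strand, ivs))
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            self.splice_introns.append((_oiv(chrom, base, sgn, b1, a2, strand), strand))
        # a "known" contig reproducing the annotated exon chain
        span = _oiv(chrom, base, sgn, exons[0][0], exons[-1][1], strand)
        self.contigs.append(nio.Contig(f"kc_{gid}", span, strand, list(ivs)))
        return ivs

    def cage_at(self, chrom, base, sgn, offs, strand, counts):
        for off, cnt in zip(offs, counts):
            self.cage.append((chrom, _opos(base, sgn, off), strand, int(cnt)))

    def sense_tags(self, chrom, base, sgn, strand):
        c1 = 1 + int(self.rng.poisson(1))
        c2 = 1 + int(self.rng.poisson(1))
        self.cage_at(chrom, base, sgn, [-15, 10], strand, [c1, c2])

    def promoter(self, chrom, center, klass, sgn, anchor, partner, gap, divergent, motif):
        self.track_plants.append((chrom, center, klass, sgn))
        self.gc_windows.append((chrom, center - 1200, center + 1200, self.cfg.gc_content[klass]))
        self.peaks.append(GenomicInterval(chrom, center - 400, center + 400, "."))
        self.truth_promoters.append(
            dict(
                anchor_gene=anchor,
                klass=klass if klass != "KBiP" else None,  # set precisely by caller
                partner=partner,
                tss_gap=gap,
                divergent=divergent,
                motif=motif,
                chrom=chrom,
                center=center,
            )
        )


def _build_slots(cfg: SimConfig, rng: np.random.Generator, bld: _Builder) -> dict[str, int]:
    """Lay every slot out; returns chromosome lengths."""
    slots: list[tuple[str, int]] = []
    for kind, n in [
        ("unip", cfg.n_unip),
        ("nbip", cfg.n_nbip),
        ("kbip_pc", cfg.n_kbip_pc),
        ("kbip_lnc", cfg.n_kbip_lnc),
        ("t2t", cfg.n_t2t),
        ("h2h", cfg.n_h2h),
        ("distal", cfg.n_distal),
        ("utr5", cfg.n_utr5),
        ("utr3", cfg.n_utr3),
        ("intex", cfg.n_internal_exon),
        ("donor", cfg.n_donor),
        ("acceptor", cfg.n_acceptor),
        ("ctx_us", cfg.n_ctx_upstream_sense),
        ("ctx_ds", cfg.n_ctx_downstream_sense),
        ("ctx_da", cfg.n_ctx_downstream_antisense),
        ("junction", cfg.n_junction),
        ("tf", 1),
    ]:
        slots.extend((kind, i + 1) for i in range(n))

    n_chrom = len(cfg.chrom_names)
    per_chrom = [0] * n_chrom
    for idx, (kind, i) in enumerate(slots):
        ci = idx % n_chrom
        chrom = cfg.chrom_names[ci]
        base = per_chrom[ci] * cfg.slot_size + ANCHOR
        per_chrom[ci] += 1
        sgn = 1 if (idx // n_chrom) % 2 == 0 else -1
        _fill_slot(cfg, rng, bld, kind, i, chrom, base, sgn)
    return {
        name: per_chrom[ci] * cfg.slot_size + 4000
        for ci, name in enumerate(cfg.chrom_names)
    }


def _fill_slot(cfg, rng, bld: _Builder, kind, i, chrom, base, sgn):
    strand = "+" if sgn > 0 else "-"
    anti = "-" if sgn > 0 else "+"

    if kind == "unip":
        gid = f"g_uni{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        bld.sense_tags(chrom, base, sgn, strand)
        bld.promoter(chrom, base, "UniP", sgn, gid, "", 0, False, False)
        if i <= int(0.6 * cfg.n_unip):
            bld.expr_trend.append((gid, None))

    elif kind == "nbip":
        gid, cid = f"g_nbp{i:04d}", f"nv_nbp{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        # half the TSS gaps below 1 kb (for the 1 kb / 2 kb sensitivity check)
        gap = int(rng.uniform(250, 950)) if i % 2 else int(rng.uniform(1050, 1800))
        span = _oiv(chrom, base, sgn, -gap - 1200, -gap, anti)
        blocks = [
            _oiv(chrom, base, sgn, -gap - 1200, -gap - 700, anti),
            _oiv(chrom, base, sgn, -gap - 500, -gap, anti),
        ]
        bld.contigs.append(nio.Contig(cid, span, anti, blocks))
        bld.splice_introns.append((_oiv(chrom, base, sgn, -gap - 700, -gap - 500, anti), anti))
        tss = base  # oriented offset 0
        cl5 = _opos(base, sgn, -gap)
        center = (tss + cl5) // 2 if sgn > 0 else (tss + cl5 + 1) // 2
        divergent = rng.random() < cfg.nbip_divergent_rate
        motif = rng.random() < cfg.motif_insertion_rate
        bld.sense_tags(chrom, base, sgn, strand)
        if divergent:
            bld.cage_at(chrom, base, sgn, [-gap - 20, -gap - 5], anti,
                        [1 + int(rng.poisson(1)), 1 + int(rng.poisson(1))])
        if motif:
            pos = int(center + rng.integers(-150, 139))
            bld.motif_sites.append((chrom, pos, strand, gid))
        bld.promoter(chrom, center, "NBiP", sgn, gid, cid, gap, divergent, motif)
        bld.truth_promoters[-1]["klass"] = "NBiP"
        program = i <= cfg.n_nbip // 2
        bld.expr_pairs.append((gid, cid, cfg.pair_r, program))
        if program:
            bld.tf_program_targets.append(cid)

    elif kind in ("kbip_pc", "kbip_lnc"):
        tag = "kbp" if kind == "kbip_pc" else "kbl"
        gl, gr = f"g_{tag}{i:04d}L", f"g_{tag}{i:04d}R"
        gap = int(rng.uniform(250, 1800))
        half = gap // 2
        # left gene on -, right gene on + : divergent pair around base
        bld.gene(gl, chrom, base - half, -1)
        if kind == "kbip_pc":
            bld.gene(gr, chrom, base + (gap - half), 1)
        else:
            bld.gene(gr, chrom, base + (gap - half), 1, biotype="lncRNA",
                     exons=[(0, LNC_LEN)])
        divergent = rng.random() < cfg.kbip_divergent_rate
        bld.sense_tags(chrom, base - half, -1, "-")
        if divergent:
            bld.sense_tags(chrom, base + (gap - half), 1, "+")
        klass = "pcKBiP" if kind == "kbip_pc" else "lncKBiP"
        anchor = gl  # smaller TSS coordinate
        center = ((base - half) + (base + gap - half)) // 2
        bld.promoter(chrom, center, "KBiP", -1, anchor, gr, gap, divergent, False)
        bld.truth_promoters[-1]["klass"] = klass
        bld.expr_pairs.append((gl, gr, cfg.kbip_r, False))

    elif kind == "t2t":
        ga, gb = f"g_t2t{i:04d}A", f"g_t2t{i:04d}B"
        # A + [-1800, 200), B - [-200, 1800): 3' ends overlap by 400 nt
        exons2 = [(0, 500), (900, 1400), (1700, 2000)]
        bld.gene(ga, chrom, base - 1800, 1, exons=exons2)
        bld.gene(gb, chrom, base + 1800, -1, exons=exons2)
        for b2, s2 in ((base - 1800, 1), (base + 1800, -1)):
            st = "+" if s2 > 0 else "-"
            bld.sense_tags(chrom, b2, s2, st)
            bld.promoter(chrom, b2, "UniP", s2,
                         ga if s2 > 0 else gb, "", 0, False, False)
        r = cfg.pair_r if i % 2 else -cfg.pair_r
        bld.expr_pairs.append((ga, gb, r, False))
        bld.truth_pairs.append(dict(sense_id=ga, antisense_id=gb,
                                    geometry="tail_to_tail", planted_r=r))
        if i <= 10:
            # contig extending A's 3' end across B (contig_extension scenario)
            blocks = [
                GenomicInterval(chrom, base - 1800 + 1700, base - 1800 + 2000, "+"),
                GenomicInterval(chrom, base + 300, base + 900, "+"),
            ]
            span = GenomicInterval(chrom, blocks[0].start, blocks[-1].end, "+")
            bld.contigs.append(nio.Contig(f"xt_t2t{i:04d}", span, "+", blocks))

    elif kind == "h2h":
        ga, gb = f"g_h2h{i:04d}A", f"g_h2h{i:04d}B"
        exons2 = [(0, 500), (900, 1400), (1700, 2000)]
        # A + [-200, 1800), B - [-1800, 200): 5' ends overlap by 400 nt
        bld.gene(ga, chrom, base - 200, 1, exons=exons2)
        bld.gene(gb, chrom, base + 200, -1, exons=exons2)
        divergent = rng.random() < cfg.kbip_divergent_rate
        bld.sense_tags(chrom, base - 200, 1, "+")
        if divergent:
            bld.sense_tags(chrom, base + 200, -1, "-")
        bld.promoter(chrom, base, "KBiP", 1, ga, gb, 400, divergent, False)
        bld.truth_promoters[-1]["klass"] = "pcKBiP"
        bld.expr_pairs.append((ga, gb, cfg.pair_r, False))
        bld.truth_pairs.append(dict(sense_id=ga, antisense_id=gb,
                                    geometry="head_to_head", planted_r=cfg.pair_r))

    elif kind == "distal":
        cid = f"nv_dst{i:04d}"
        blocks = [
            _oiv(chrom, base, sgn, -1000, -200, strand),
            _oiv(chrom, base, sgn, 200, 1000, strand),
        ]
        span = _oiv(chrom, base, sgn, -1000, 1000, strand)
        bld.contigs.append(nio.Contig(cid, span, strand, blocks))
        bld.splice_introns.append((_oiv(chrom, base, sgn, -200, 200, strand), strand))
        if rng.random() < cfg.distal_trend_rate:
            shape = "down" if rng.random() < 0.85 else "up"
            bld.expr_trend.append((cid, shape))

    elif kind in ("utr5", "utr3"):
        gid = f"g_{kind}{i:04d}"
        cid = f"nv_{kind}{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        ext = int(rng.uniform(150, 600))
        if kind == "utr5":
            blocks = [_oiv(chrom, base, sgn, -ext, 400, strand),
                      _oiv(chrom, base, sgn, 900, 1500, strand)]
            span = _oiv(chrom, base, sgn, -ext, 1500, strand)
            bld.peaks.append(_oiv(chrom, base, sgn, -ext - 400, -ext - 100, "."))
            iv = _oiv(chrom, base, sgn, -ext, 0, strand)
        else:
            blocks = [_oiv(chrom, base, sgn, 900, 1500, strand),
                      _oiv(chrom, base, sgn, 2100, 2500 + ext, strand)]
            span = _oiv(chrom, base, sgn, 900, 2500 + ext, strand)
            p = _opos(base, sgn, 2500 + ext + 10)
            bld.polya.append(GenomicInterval(chrom, p, p + 1, strand))
            iv = _oiv(chrom, base, sgn, 2500, 2500 + ext, strand)
        contig = nio.Contig(cid, span, strand, blocks)
        bld.contigs.append(contig)
        in_alt = rng.random() < 0.8
        if in_alt:
            bld.alt_contigs.append(contig)
        bld.truth_elements.append(dict(
            gene=gid, kind=f"{kind}_extension", start=iv.start, end=iv.end,
            chrom=chrom, contig=cid, in_alt=in_alt))

    elif kind == "intex":
        gid, cid = f"g_iex{i:04d}", f"nv_iex{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        nov = _oiv(chrom, base, sgn, 550, 750, strand)
        blocks = [_oiv(chrom, base, sgn, 0, 400, strand), nov,
                  _oiv(chrom, base, sgn, 900, 1500, strand)]
        span = _oiv(chrom, base, sgn, 0, 1500, strand)
        bld.splice_introns.append((_oiv(chrom, base, sgn, 400, 550, strand), strand))
        bld.splice_introns.append((_oiv(chrom, base, sgn, 750, 900, strand), strand))
        contig = nio.Contig(cid, span, strand, blocks)
        bld.contigs.append(contig)
        in_alt = rng.random() < 0.8
        if in_alt:
            bld.alt_contigs.append(contig)
        bld.truth_elements.append(dict(
            gene=gid, kind="novel_internal_exon", start=nov.start, end=nov.end,
            chrom=chrom, contig=cid, in_alt=in_alt))

    elif kind in ("donor", "acceptor"):
        gid, cid = f"g_{kind[:3]}{i:04d}", f"nv_{kind[:3]}{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        if kind == "donor":
            blk = _oiv(chrom, base, sgn, 900, 1800, strand)  # shares e2 start
            bld.splice_introns.append((_oiv(chrom, base, sgn, 1800, 2100, strand), strand))
            iv = blk
        else:
            blk = _oiv(chrom, base, sgn, 600, 1500, strand)  # shares e2 end
            bld.splice_introns.append((_oiv(chrom, base, sgn, 400, 600, strand), strand))
            iv = blk
        blocks = [_oiv(chrom, base, sgn, 0, 400, strand), blk,
                  _oiv(chrom, base, sgn, 2100, 2500, strand)]
        span = _oiv(chrom, base, sgn, 0, 2500, strand)
        contig = nio.Contig(cid, span, strand, blocks)
        bld.contigs.append(contig)
        in_alt = rng.random() < 0.8
        if in_alt:
            bld.alt_contigs.append(contig)
        bld.truth_elements.append(dict(
            gene=gid, kind=f"novel_{kind}", start=iv.start, end=iv.end,
            chrom=chrom, contig=cid, in_alt=in_alt))

    elif kind.startswith("ctx_"):
        gid = f"g_{kind[4:]}{i:04d}"
        bld.gene(gid, chrom, base, sgn)
        cid = f"nv_{kind[4:]}{i:04d}"
        d = int(rng.uniform(1200, 3500))
        if kind == "ctx_us":
            span = _oiv(chrom, base, sgn, -d - 1000, -d, strand)
            cstrand, category, r = strand, "upstream_sense", cfg.ctx_r
        elif kind == "ctx_ds":
            span = _oiv(chrom, base, sgn, GENE_LEN + d, GENE_LEN + d + 1000, strand)
            cstrand, category, r = strand, "downstream_sense", cfg.ctx_r
        else:
            span = _oiv(chrom, base, sgn, GENE_LEN + d, GENE_LEN + d + 1000, anti)
            cstrand, category, r = anti, "downstream_antisense", 0.0
        bld.contigs.append(nio.Contig(cid, span, cstrand, [dataclasses.replace(span)]))
        bld.truth_context.append(dict(contig=cid, gene=gid, category=category,
                                      distance=d, planted_r=r))
        if r != 0:
            bld.expr_pairs.append((gid, cid, r, False))
        else:
            bld.expr_trend.append((gid, None))

    elif kind == "junction":
        gn, gs = f"g_jct{i:04d}N", f"g_jct{i:04d}S"
        cid = f"nv_jct{i:04d}"
        b0 = base - ANCHOR  # slot start
        n_exons = bld.gene(gn, chrom, b0 + 2000, 1)
        bld.gene(gs, chrom, b0 + 10500, -1)
        blocks = [GenomicInterval(chrom, b0 + 5200, b0 + 6000, "+"),
                  GenomicInterval(chrom, b0 + 6400, b0 + 8800, "+")]
        span = GenomicInterval(chrom, b0 + 5200, b0 + 8800, "+")
        bld.contigs.append(nio.Contig(cid, span, "+", blocks))
        bld.splice_introns.append(
            (GenomicInterval(chrom, b0 + 6000, b0 + 6400, "+"), "+"))
        donor = n_exons[1].end  # annotated donor of gene N's second exon
        bld.junctions.append((chrom, donor, b0 + 5200, "+"))
        bld.splice_introns.append(
            (GenomicInterval(chrom, donor, b0 + 5200, "+"), "+"))
        bld.truth_links.append(dict(contig=cid, gene=gn))
        r = cfg.ctx_r if i % 2 else -cfg.ctx_r
        bld.expr_pairs.append((gn, gs, r, False))
        bld.truth_pairs.append(dict(sense_id=gn, antisense_id=gs,
                                    geometry="tail_to_tail", planted_r=r))

    elif kind == "tf":
        bld.gene("g_tf0001", chrom, base, sgn)

    else:  # pragma: no cover
        raise AssertionError(kind)


# ---------------------------------------------------------------------------
# genome sequence


def _random_bases(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _build_genome(cfg, rng, bld, chrom_lens) -> dict[str, str]:
    genome = {c: _random_bases(rng, n, cfg.background_gc) for c, n in chrom_lens.items()}
    code = {b: k for k, b in enumerate(BASES)}
    for chrom, start, end, gc in bld.gc_windows:
        genome[chrom][start:end] = _random_bases(rng, end - start, gc)
    for iv, strand in bld.splice_introns:
        seq = genome[iv.chrom]
        if strand == "+":
            seq[iv.start], seq[iv.start + 1] = code["G"], code["T"]
            seq[iv.end - 2], seq[iv.end - 1] = code["A"], code["G"]
        else:
            seq[iv.end - 2], seq[iv.end - 1] = code["A"], code["C"]
            seq[iv.start], seq[iv.start + 1] = code["C"], code["T"]
    return genome


def _plant_motifs(cfg, rng, bld, genome, consensus: str):
    code = {b: k for k, b in enumerate(BASES)}
    for chrom, pos, strand, _gid in bld.motif_sites:
        seq = consensus if strand == "+" else revcomp(consensus)
        planted = []
        for b in seq:
            if rng.random() < cfg.motif_mutation_p:
                b = str(rng.choice([x for x in "ACGT" if x != b]))
            planted.append(b)
        genome[chrom][pos : pos + len(seq)] = [code[b] for b in planted]


def _write_pwms(cfg, rng, path, consensus: str) -> list[str]:
    """TRANSFAC-format library: the planted matrix first, then decoys."""
    ids = []
    with open(path, "w") as fh:
        fh.write("VV  nbipscan synthetic matrix library\n//\n")
        for k in range(1 + cfg.n_decoy_matrices):
            if k == 0:
                mid, seq = "M00001_SYNTF1", consensus
            else:
                mid = f"M{k + 1:05d}_DECOY{k}"
                seq = "".join(rng.choice(list("ACGT"), size=12))
            ids.append(mid)
            fh.write(f"ID  {mid}\nBF  {mid.split('_')[1]}\n")
            fh.write("P0      A      C      G      T\n")
            for p, b in enumerate(seq, start=1):
                row = {x: 1 for x in "ACGT"}
                row[b] = 12
                fh.write(f"{p:02d} {row['A']:6d} {row['C']:6d} {row['G']:6d} {row['T']:6d}  {b}\n")
            fh.write("//\n")
    return ids


# ---------------------------------------------------------------------------
# expression


def _trajectory(rng, x, shape=None):
    if shape is None:
        shape = str(rng.choice(["down", "up", "peak", "cubic"]))
    if shape == "down":
        v = -x
    elif shape == "up":
        v = x
    elif shape == "peak":
        v = -(x**2)
    else:
        v = x**3 - x
    v = (v - v.mean()) / v.std()
    return v, shape


def _build_expression(cfg, rng, bld, ages) -> tuple[list[str], np.ndarray, list[dict]]:
    x = np.log2(ages + 1)
    x = (x - x.mean()) / x.std()
    gene_ids = [g for g, *_ in bld.gtf_rows]
    novel_ids = sorted(
        c.name for c in bld.contigs if c.name.startswith(("nv_", "xt_"))
    )
    ids = gene_ids + novel_ids
    idx = {t: k for k, t in enumerate(ids)}
    n = len(ids)
    logv = np.empty((n, cfg.n_samples))
    mu = cfg.expr_mu + cfg.expr_mu_sd * rng.standard_normal(n)
    noise = rng.standard_normal((n, cfg.n_samples))
    logv[:] = mu[:, None] + cfg.expr_sd * noise

    z_tf, _ = _trajectory(rng, x, "peak")
    truth_trend: list[dict] = []

    for tid, shape in bld.expr_trend:
        z, shape = _trajectory(rng, x, shape)
        k = idx[tid]
        y = 0.8 * z + 0.6 * rng.standard_normal(cfg.n_samples)
        logv[k] = mu[k] + cfg.expr_sd * y
        truth_trend.append(dict(id=tid, shape=shape, paired=False))

    for id1, id2, r, program in bld.expr_pairs:
        z = z_tf if program else _trajectory(rng, x)[0]
        a = np.sqrt(abs(r))
        for tid, sign in ((id1, 1.0), (id2, np.sign(r) if r != 0 else 1.0)):
            k = idx[tid]
            y = sign * a * z + np.sqrt(1 - a**2) * rng.standard_normal(cfg.n_samples)
            logv[k] = mu[k] + cfg.expr_sd * y
            truth_trend.append(dict(id=tid, shape="pair", paired=True))

    k = idx["g_tf0001"]
    logv[k] = mu[k] + cfg.expr_sd * (
        0.95 * z_tf + 0.31 * rng.standard_normal(cfg.n_samples)
    )
    rpkm = np.maximum(2.0**logv - 0.1, 0.0)
    return ids, rpkm, truth_trend


# ---------------------------------------------------------------------------
# tracks


def _build_tracks(cfg, rng, bld, chrom_lens) -> dict[str, SignalTrack]:
    tracks = {k: SignalTrack(kind=k) for k in
              ("h3k4me3", "input", "methylation", "phastcons", "rp_score")}
    w, b = 1250, cfg.track_bin
    offs = np.arange(-w, w, b)
    centers = offs + b / 2
    for chrom, center, klass, sgn in sorted(bld.track_plants, key=lambda t: (t[0], t[1])):
        starts = center + offs
        ends = starts + b
        if starts[0] < 0 or ends[-1] > chrom_lens[chrom]:
            continue
        delta = {"UniP": 600.0, "NBiP": 120.0, "KBiP": 0.0}[klass]
        delta *= cfg.h3k4me3_asymmetry * sgn
        bump = np.exp(-((centers - delta) ** 2) / (2 * 500.0**2))
        noise = np.exp(cfg.track_noise_sd * rng.standard_normal(len(offs)))
        tracks["h3k4me3"].add_segments(
            chrom, starts, ends, cfg.h3k4me3_amp[klass] * bump * noise)
        tracks["input"].add_segments(
            chrom, starts, ends,
            np.exp(cfg.track_noise_sd * rng.standard_normal(len(offs))))
        tracks["methylation"].add_segments(
            chrom, starts, ends,
            np.clip(cfg.methylation_means[klass]
                    + 0.05 * rng.standard_normal(len(offs)), 0, 1))
        tracks["phastcons"].add_segments(
            chrom, starts, ends,
            np.clip(cfg.phastcons_means[klass]
                    + 0.08 * rng.standard_normal(len(offs)), 0, 1))
        tracks["rp_score"].add_segments(
            chrom, starts, ends,
            cfg.rp_means[klass] + 0.1 * rng.standard_normal(len(offs)))
    for t in tracks.values():
        t.finalize()
    return tracks


# ---------------------------------------------------------------------------
# entry point


def simulate(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate the full file set; returns a name -> path mapping."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    bld = _Builder(config, rng)
    chrom_lens = _build_slots(config, rng, bld)

    for chrom, n in chrom_lens.items():
        used = max(
            [e.end for r in bld.gtf_rows for e in r[3] if e.chrom == chrom]
            + [c.span.end for c in bld.contigs if c.span.chrom == chrom],
            default=0,
        )
        if used > n:
            raise ValueError(
                f"genome too small for requested feature counts: {chrom} needs "
                f">= {used} nt, has {n}")

    genome = _build_genome(config, rng, bld, chrom_lens)
    consensus = "".join(rng.choice(list("ACGT"), size=12))
    _plant_motifs(config, rng, bld, genome, consensus)

    ages = default_ages(config.n_samples, config.age_min_days, config.age_max_days)
    ids, rpkm, truth_trend = _build_expression(config, rng, bld, ages)
    tracks = _build_tracks(config, rng, bld, chrom_lens)

    paths: dict[str, Path] = {}

    def reg(name, fname):
        paths[name] = outdir / fname
        return paths[name]

    ascii_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    nio.write_fasta(
        {c: bytes(ascii_map[genome[c]]).decode("ascii") for c in config.chrom_names},
        reg("fasta", "genome.fa"))

    from .intervals import GeneModel

    genes = [
        GeneModel(gene_id=gid, biotype=bt, strand=st, transcripts=[ivs])
        for gid, bt, st, ivs in bld.gtf_rows
    ]
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    nio.write_annotation(genes, reg("gtf", "annotation.gtf"))
    nio.write_bed12(bld.contigs, reg("contigs", "contigs.bed12"))
    nio.write_bed12(bld.alt_contigs, reg("alt_contigs", "alt_contigs.bed12"))

    nio.write_cage(CageTags.from_records(bld.cage), reg("cage", "cage.bed"))
    for kind, fname in [("h3k4me3", "h3k4me3.bedgraph"), ("input", "input.bedgraph"),
                        ("methylation", "methylation.bedgraph"),
                        ("phastcons", "phastcons.bedgraph"),
                        ("rp_score", "rp.bedgraph")]:
        nio.write_bedgraph(tracks[kind], reg(kind, fname))
    nio.write_bed6(((iv, "peak", 0) for iv in bld.peaks), reg("peaks", "h3k4me3_peaks.bed"))
    nio.write_bed6(((iv, "polya", 0) for iv in bld.polya), reg("polya", "polya_sites.bed"))
    nio.write_junctions(bld.junctions, reg("junctions", "junctions.tsv"))
    _write_pwms(config, rng, reg("pwms", "matrices.dat"), consensus)

    with open(reg("tf_map", "tf_map.tsv"), "w") as fh:
        fh.write("matrix_id\ttf_gene\nM00001_SYNTF1\tg_tf0001\n")

    # expression table: first row after the header carries sample ages (days)
    with open(reg("expression", "expression.tsv"), "w") as fh:
        samples = [f"s{j + 1:02d}" for j in range(config.n_samples)]
        fh.write("id\t" + "\t".join(samples) + "\n")
        fh.write("age_days\t" + "\t".join(f"{a:.6g}" for a in ages) + "\n")
        for k, tid in enumerate(ids):
            fh.write(tid + "\t" + "\t".join(f"{v:.6g}" for v in rpkm[k]) + "\n")

    # neuron / non-neuron flags: NBiP-anchored genes biased towards N
    nbip_genes = {t["anchor_gene"] for t in bld.truth_promoters if t["klass"] == "NBiP"}
    with open(reg("neuron_flags", "neuron_flags.tsv"), "w") as fh:
        fh.write("gene_id\tflag\n")
        for g in genes:
            p = 0.85 if g.gene_id in nbip_genes else 0.4
            fh.write(f"{g.gene_id}\t{'N' if rng.random() < p else 'nonN'}\n")

    # tissue panel: distal novel contigs tissue-specific, genes broad
    tissues = [f"tissue{j + 1}" for j in range(config.n_tissues)]
    with open(reg("tissue_panel", "tissue_panel.tsv"), "w") as fh:
        fh.write("id\t" + "\t".join(tissues) + "\n")
        for tid in ids:
            if tid.startswith("nv_dst"):
                vals = np.full(config.n_tissues, 0.01)
                vals[rng.integers(config.n_tissues)] = 5.0
            elif tid.startswith("nv_"):
                vals = np.where(rng.random(config.n_tissues) < 0.4,
                                rng.uniform(1, 4, config.n_tissues), 0.01)
            else:
                vals = rng.uniform(2, 4, config.n_tissues)
            fh.write(tid + "\t" + "\t".join(f"{v:.4g}" for v in vals) + "\n")

    # per-gene sense/antisense read counts for strandedness QC
    with open(reg("strand_counts", "strand_counts.tsv"), "w") as fh:
        samples = [f"s{j + 1:02d}" for j in range(config.n_samples)]
        fh.write("gene_id\tsample\tsense\tantisense\n")
        for g in genes:
            tot = rng.poisson(200, size=config.n_samples) + 1
            sense = rng.binomial(tot, config.strandedness)
            for s, t_, sc in zip(samples, tot, sense):
                fh.write(f"{g.gene_id}\t{s}\t{sc}\t{t_ - sc}\n")

    # ---- truth tables -----------------------------------------------------
    import pandas as pd

    pd.DataFrame(bld.truth_promoters).to_csv(
        reg("truth_promoters", "truth/promoters.tsv"), sep="\t", index=False)
    pd.DataFrame(bld.truth_pairs).to_csv(
        reg("truth_pairs", "truth/pairs.tsv"), sep="\t", index=False)
    pd.DataFrame(bld.truth_context).to_csv(
        reg("truth_context", "truth/context.tsv"), sep="\t", index=False)
    pd.DataFrame(bld.truth_elements).to_csv(
        reg("truth_elements", "truth/elements.tsv"), sep="\t", index=False)
    pd.DataFrame(bld.truth_links).to_csv(
        reg("truth_links", "truth/junction_links.tsv"), sep="\t", index=False)
    pd.DataFrame(truth_trend).to_csv(
        reg("truth_trends", "truth/age_trends.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [dict(matrix_id="M00001_SYNTF1", chrom=c, pos=p, strand=s, anchor_gene=g)
         for c, p, s, g in bld.motif_sites]
    ).to_csv(reg("truth_motifs", "truth/motifs.tsv"), sep="\t", index=False)
    with open(reg("truth_config", "truth/config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=list)

    log.info("simulated %d genes, %d contigs over %s",
             len(genes), len(bld.contigs),
             {c: f"{n / 1e6:.2f} Mb" for c, n in chrom_lens.items()})
    return paths
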