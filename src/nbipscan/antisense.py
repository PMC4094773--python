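"""Sense/antisense gene pairs: discovery, junction support, correlation contrast.

Opposite-strand gene pairs are classed by which termini meet: overlap (or
facing) at both 3' ends is tail-to-tail, at both 5' ends head-to-head.
Three (non-exclusive) discovery scenarios are supported: annotated overlap,
overlap created by a contig extending one gene into the other, and splice
junctions joining a novel cluster to an annotated splice site of a
neighboring gene. Expression correlation of pairs is contrasted with
nearest non-overlapping opposite-strand control pairs via kernel densities
and a 100-subsample difference band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .intervals import ContigCluster, GeneModel, GenomicInterval
from .stats import log_expr, pearson_rows

log = logging.getLogger(__name__)

MIN_MEAN_RPKM = 0.1


def pair_geometry(span_a: GenomicInterval, strand_a: str,
                  span_b: GenomicInterval, strand_b: str) -> str | None:
    """head_to_head / tail_to_tail / None for an opposite-strand pair.

    Overlapping spans: mutual containment of the 5' (3') termini in the
    partner span decides; disjoint spans: the facing boundaries must both be
    5' (3') ends. Nested or same-strand configurations return None.
    """
    if strand_a == strand_b or span_a.chrom != span_b.chrom:
        return None
    five_a = span_a.start if strand_a == "+" else span_a.end
    three_a = span_a.end if strand_a == "+" else span_a.start
    five_b = span_b.start if strand_b == "+" else span_b.end
    three_b = span_b.end if strand_b == "+" else span_b.start

    if span_a.overlaps(span_b):
        def inside(pos, span):
            return span.start <= pos <= span.end
        h2h = inside(five_a, span_b) and inside(five_b, span_a)
        t2t = inside(three_a, span_b) and inside(three_b, span_a)
        if h2h and t2t:
            return ("head_to_head" if abs(five_a - five_b) <= abs(three_a - three_b)
                    else "tail_to_tail")
        if h2h:
            return "head_to_head"
        if t2t:
            return "tail_to_tail"
        return None
    left, lstr, right, rstr = (
        (span_a, strand_a, span_b, strand_b)
        if span_a.start <= span_b.start
        else (span_b, strand_b, span_a, strand_a))
    if (lstr, rstr) == ("-", "+"):
        return "head_to_head"
    if (lstr, rstr) == ("+", "-"):
        return "tail_to_tail"
    return None


@dataclass
class SasPair:
    sense_id: str
    antisense_id: str
    geometry: str
    scenario: set = field(default_factory=set)
    pearson_r: float = float("nan")


def _splice_sites(gene: GeneModel) -> tuple[set[int], set[int]]:
    """(donor positions, acceptor positions) in genome coordinates."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for tx in gene.transcripts:
        for a, b in zip(tx, tx[1:]):
            if gene.strand == "+":
                donors.add(a.end)
                acceptors.add(b.start)
            else:
                donors.add(b.start)
                acceptors.add(a.end)
    return donors, acceptors


def junction_links(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    junctions: list[tuple[str, int, int, str]],
) -> tuple[list[tuple[str, str]], int]:
    """(cluster_id, gene_id) links where a junction joins a novel cluster to
    an annotated splice site; also returns the count of unmatched junctions."""
    site_index: dict[tuple[str, str, int], list[GeneModel]] = {}
    for g in genes:
        donors, acceptors = _splice_sites(g)
        for pos in donors | acceptors:
            site_index.setdefault((g.chrom, g.strand, pos), []).append(g)

    novel = [c for c in clusters if c.status == "novel"]
    links: set[tuple[str, str]] = set()
    unmatched = 0
    for chrom, start, end, strand in junctions:
        hits = []
        for pos, other in ((start, end), (end, start)):
            for g in site_index.get((chrom, strand, pos), []):
                hits.append((g, other))
        if not hits:
            unmatched += 1
            continue
        for g, other in hits:
            for c in novel:
                if (c.chrom == chrom and c.strand == strand
                        and c.span.start <= other <= c.span.end):
                    links.add((c.cluster_id, g.gene_id))
    if unmatched:
        log.info("%d junctions matched no annotated splice site", unmatched)
    return sorted(links), unmatched


def find_sas_pairs(
    genes: list[GeneModel],
    clusters: list[ContigCluster],
    junctions: list[tuple[str, int, int, str]] | None = None,
    expression: "object | None" = None,
    min_mean_rpkm: float = MIN_MEAN_RPKM,
) -> list[SasPair]:
    """Identify sense/antisense gene pairs under the three scenarios.

    ``expression`` (optional, any object with ``mean_of(id)``) filters genes
    below ``min_mean_rpkm``. Complex loci where more than two genes share one
    overlap pattern are removed.
    """
    if expression is not None:
        genes = [g for g in genes
                 if (m := expression.mean_of(g.gene_id)) is not None
                 and m >= min_mean_rpkm]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_by_id = {g.gene_id: g for g in genes}

    pairs: dict[tuple[str, str], SasPair] = {}

    def add(ga: GeneModel, gb: GeneModel, scenario: str):
        geom = pair_geometry(ga.span, ga.strand, gb.span, gb.strand)
        if geom is None:
            return
        a, b = sorted([ga.gene_id, gb.gene_id])
        pair = pairs.setdefault((a, b), SasPair(a, b, geom))
        pair.scenario.add(scenario)

    # scenario 1: annotated overlap
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.span.start)
        for i, ga in enumerate(gs):
            for gb in gs[i + 1:]:
                if gb.span.start >= ga.span.end:
                    break
                if gb.strand != ga.strand:
                    add(ga, gb, "annotated")

    # scenario 2: contig extending a gene overlaps an opposite-strand gene
    for cl in clusters:
        if cl.status != "known":
            continue
        host = [g for g in by_chrom.get(cl.chrom, [])
                if g.strand == cl.strand and g.span.overlaps(cl.span)]
        if not host:
            continue
        extends = [g for g in host
                   if cl.span.start < g.span.start or cl.span.end > g.span.end]
        if not extends:
            continue
        for g in extends:
            for gb in by_chrom.get(cl.chrom, []):
                if gb.strand != cl.strand and gb.span.overlaps(cl.span):
                    add(g, gb, "contig_extension")

    # scenario 3: junction-supported links
    if junctions:
        links, _ = junction_links(clusters, [g for g in genes], junctions)
        cl_by_id = {c.cluster_id: c for c in clusters}
        for cid, gid in links:
            cl = cl_by_id[cid]
            host = gene_by_id.get(gid)
            if host is None:
                continue
            for gb in by_chrom.get(cl.chrom, []):
                if gb.strand != cl.strand and gb.span.overlaps(cl.span):
                    add(host, gb, "junction_supported")

    # complex-locus removal: >2 genes sharing one overlap pattern
    out = list(pairs.values())
    for geom in ("head_to_head", "tail_to_tail"):
        degree: dict[str, int] = {}
        for p in out:
            if p.geometry == geom:
                degree[p.sense_id] = degree.get(p.sense_id, 0) + 1
                degree[p.antisense_id] = degree.get(p.antisense_id, 0) + 1
        bad = {g for g, d in degree.items() if d > 1}
        if bad:
            log.info("removing %d genes in complex %s loci", len(bad), geom)
        out = [p for p in out
               if p.geometry != geom
               or (p.sense_id not in bad and p.antisense_id not in bad)]
    out.sort(key=lambda p: (p.sense_id, p.antisense_id))
    return out


def _intergenic_space(genes: list[GeneModel], chrom_lens: dict[str, int]):
    """Per-chromosome sorted gene-free intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in chrom_lens.items():
        spans = sorted((g.span.start, g.span.end) for g in genes if g.chrom == chrom)
        free = []
        cur = 0
        for s, e in spans:
            if s > cur:
                free.append((cur, s))
            cur = max(cur, e)
        if cur < length:
            free.append((cur, length))
        out[chrom] = free
    return out


def _random_placement(rng, clusters, free_by_chrom):
    """Relocate clusters to random intergenic starts (chrom & strand kept)."""
    placed = []
    for cl in clusters:
        free = free_by_chrom.get(cl.chrom, [])
        lens = np.array([e - s for s, e in free], dtype=float)
        size = len(cl.span)
        ok = lens > size
        if not ok.any():
            raise ValueError(f"no intergenic space fits cluster {cl.cluster_id}")
        w = np.where(ok, lens - size, 0.0)
        i = int(rng.choice(len(free), p=w / w.sum()))
        s0, e0 = free[i]
        start = int(rng.integers(s0, e0 - size))
        placed.append((cl, start))
    return placed


def expected_junction_links(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    junctions: list[tuple[str, int, int, str]],
    chrom_lens: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Null expectation for junction-supported links under random cluster placement.

    Clusters are relocated uniformly into intergenic space, preserving
    per-chromosome and per-strand counts; returns the observed count, the
    null mean, and the empirical p-value (1 + #null >= obs) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    novel = [c for c in clusters if c.status == "novel"]
    observed = len(junction_links(novel, genes, junctions)[0])
    free = _intergenic_space(genes, chrom_lens)

    # precompute junction ends matching annotated splice sites
    site_index = set()
    for g in genes:
        d, a = _splice_sites(g)
        for pos in d | a:
            site_index.add((g.chrom, g.strand, pos))
    anchored = []  # (chrom, strand, other-end position)
    for chrom, start, end, strand in junctions:
        if (chrom, strand, start) in site_index:
            anchored.append((chrom, strand, end))
        if (chrom, strand, end) in site_index:
            anchored.append((chrom, strand, start))

    null = np.zeros(n_perm)
    for k in range(n_perm):
        placed = _random_placement(rng, novel, free)
        count = 0
        for chrom, strand, pos in anchored:
            for cl, start in placed:
                if (cl.chrom == chrom and cl.strand == strand
                        and start <= pos <= start + len(cl.span)):
                    count += 1
                    break
        null[k] = count
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {"observed": observed, "null_mean": float(null.mean()), "p": p,
            "null": null}


@dataclass
class DensityContrast:
    geometry: str
    grid: np.ndarray
    observed_density: np.ndarray
    control_density: np.ndarray
    control_curves: np.ndarray  # (n_subsamples, len(grid))
    difference: np.ndarray
    difference_band: np.ndarray  # (2, len(grid)) lower/upper of subsample diffs
    pair_r: np.ndarray
    control_r: np.ndarray


def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Silverman-bandwidth Gaussian KDE renormalized to integrate to 1 on grid."""
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    return dens / area


def nearest_control_pairs(genes: list[GeneModel]) -> list[tuple[str, str]]:
    """Nearest non-overlapping opposite-strand gene pair for every gene.

    Distance is between span midpoints; ties break to the lower-coordinate
    candidate. Returned pairs are deduplicated.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = set()
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.span.start)
        mids = np.array([(g.span.start + g.span.end) / 2 for g in gs])
        for i, g in enumerate(gs):
            best = None
            for j, h in enumerate(gs):
                if j == i or h.strand == g.strand or h.span.overlaps(g.span):
                    continue
                d = abs(mids[j] - mids[i])
                key = (d, h.span.start, h.gene_id)
                if best is None or key < best[0]:
                    best = (key, h)
            if best is not None:
                pairs.add(tuple(sorted([g.gene_id, best[1].gene_id])))
    return sorted(pairs)


def correlation_contrast(
    pairs: list[SasPair],
    expression,
    genes: list[GeneModel],
    n_subsamples: int = 100,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> dict[str, DensityContrast]:
    """Pair-vs-control Pearson-r density contrast per geometry.

    ``expression`` must expose ``matrix_for(ids) -> (ids_found, values)``.
    Controls are sampled ``n_subsamples`` times at the pair count; the band is
    the per-grid-point min/max of the subsample-minus-control differences.
    """
    if expression.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation analysis")
    if grid is None:
        grid = np.linspace(-1, 1, 201)
    rng = np.random.default_rng(seed)

    def pair_r_values(id_pairs):
        rs = []
        for a, b in id_pairs:
            va = expression.vector(a)
            vb = expression.vector(b)
            if va is None or vb is None:
                continue
            la, lb = log_expr(va), log_expr(vb)
            if la.std() == 0 or lb.std() == 0:
                log.info("zero-variance expression for pair (%s, %s); dropped", a, b)
                continue
            rs.append(float(np.corrcoef(la, lb)[0, 1]))
        return np.array(rs)

    controls = nearest_control_pairs(genes)
    control_r = pair_r_values(controls)

    out = {}
    for geom in ("tail_to_tail", "head_to_head"):
        sel = [p for p in pairs if p.geometry == geom]
        obs_r = pair_r_values([(p.sense_id, p.antisense_id) for p in sel])
        for p, r in zip(sel, obs_r):
            p.pearson_r = r
        if len(obs_r) < 3 or len(control_r) < 3:
            continue
        obs_d = _kde_on_grid(obs_r, grid)
        ctl_d = _kde_on_grid(control_r, grid)
        curves = np.empty((n_subsamples, len(grid)))
        n_draw = min(len(obs_r), len(control_r))
        for k in range(n_subsamples):
            sub = rng.choice(control_r, size=n_draw, replace=True)
            curves[k] = _kde_on_grid(sub, grid)
        diffs = curves - ctl_d
        out[geom] = DensityContrast(
            geometry=geom,
            grid=grid,
            observed_density=obs_d,
            control_density=ctl_d,
            control_curves=curves,
            difference=obs_d - ctl_d,
            difference_band=np.vstack([diffs.min(axis=0), diffs.max(axis=0)]),
            pair_r=obs_r,
            control_r=control_r,
        )
    return out
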