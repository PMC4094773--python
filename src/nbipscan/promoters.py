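"""Genomic-context classification of novel clusters and promoter typing.

Intergenic novel clusters are assigned to one of four categories relative to
the nearest annotated gene within a distance cutoff — upstream-sense,
downstream-sense, upstream-antisense, downstream-antisense — with the cutoff
either fixed (default 4 kb) or estimated by permuting cluster positions
along each chromosome. Promoters are then typed:

* NBiP  — annotated gene head-to-head with a *novel* cluster, TSS-to-TSS
  within ``bidir_window`` (default 2 kb);
* pcKBiP / lncKBiP — same geometry with an annotated protein-coding or
  lncRNA partner;
* UniP  — no annotated transcript or cluster within ``unip_window``
  (default 5 kb) upstream of the TSS.

CAGE tags aggregated per strand over the promoter window supply divergence
evidence: divergent requires >= 1 tag on each strand; confirmed
unidirectional requires >= 2 sense tags and 0 antisense tags. Promoters with
no tags are excluded from divergence statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .antisense import _intergenic_space, _random_placement, pair_geometry
from .intervals import CageTags, ContigCluster, GeneModel, GenomicInterval
from .stats import bh_adjust, fisher_enrichment, log_expr

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4000
BIDIR_WINDOW = 2000
UNIP_WINDOW = 5000


@dataclass
class ContextCall:
    cluster_id: str
    partner_gene_id: str
    category: str
    distance: int
    pearson_r: float = float("nan")
    bh_q: float = float("nan")


@dataclass
class PromoterCall:
    anchor_gene_id: str
    tss: int
    chrom: str
    strand: str
    partner_id: str | None
    klass: str  # UniP | pcKBiP | lncKBiP | NBiP
    window: GenomicInterval
    cage_sense: int = 0
    cage_antisense: int = 0
    has_cage: bool = False
    divergent: bool = False
    unidirectional_confirmed: bool = False


# ---------------------------------------------------------------------------
# distance cutoff


def _nearest_gene_distances(positions, genes_by_chrom):
    """Distance from each (chrom, start, end) span to the nearest gene span."""
    out = []
    for chrom, start, end in positions:
        bounds = genes_by_chrom.get(chrom)
        if bounds is None or len(bounds) == 0:
            out.append(np.inf)
            continue
        starts, ends = bounds
        i = np.searchsorted(starts, end)
        d = np.inf
        if i > 0:
            d = min(d, max(0, start - ends[: i].max()))
        if i < len(starts):
            d = min(d, max(0, starts[i] - end))
        # overlap => distance 0 handled by max(0, .)
        out.append(d)
    return np.array(out)


def _gene_bounds(genes):
    by_chrom = {}
    for chrom in {g.chrom for g in genes}:
        spans = sorted((g.span.start, g.span.end) for g in genes if g.chrom == chrom)
        by_chrom[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )
    return by_chrom


def intergenic_clusters(clusters, genes, min_rpkm: float = 0.1):
    """Novel clusters not overlapping any gene span (either strand), with
    mean expression above ``min_rpkm`` where expression is attached."""
    by_chrom = _gene_bounds(genes)
    out = []
    for cl in clusters:
        if cl.status != "novel":
            continue
        if cl.mean_rpkm is not None and cl.mean_rpkm < min_rpkm:
            continue
        bounds = by_chrom.get(cl.chrom)
        if bounds is not None:
            starts, ends = bounds
            i = np.searchsorted(starts, cl.span.end)
            if i > 0 and ends[:i].max() > cl.span.start:
                continue
        out.append(cl)
    return out


def estimate_distance_cutoff(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    chrom_lens: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    grid_step: int = 250,
    max_distance: int = 10000,
    alpha: float = 0.05,
    default: int = DEFAULT_CUTOFF,
) -> int:
    """Largest distance d at which the observed cluster-gene pair count
    exceeds random-placement expectation at empirical p < ``alpha``.

    Permutations relocate clusters into intergenic space keeping
    per-chromosome, per-strand counts. Returns ``default`` (with a warning)
    when no grid distance is significant.
    """
    inter = intergenic_clusters(clusters, genes)
    if len(inter) < 10:
        raise ValueError(
            f"only {len(inter)} intergenic clusters; too few to estimate a "
            f"cutoff — use the fixed default ({default} nt)")
    rng = np.random.default_rng(seed)
    gb = _gene_bounds(genes)
    obs_d = _nearest_gene_distances(
        [(c.chrom, c.span.start, c.span.end) for c in inter], gb)
    grid = np.arange(grid_step, max_distance + 1, grid_step)
    obs_counts = (obs_d[:, None] <= grid[None, :]).sum(axis=0)

    free = _intergenic_space(genes, chrom_lens)
    null_counts = np.zeros((n_perm, len(grid)), dtype=int)
    for k in range(n_perm):
        placed = _random_placement(rng, inter, free)
        d = _nearest_gene_distances(
            [(c.chrom, s, s + len(c.span)) for c, s in placed], gb)
        null_counts[k] = (d[:, None] <= grid[None, :]).sum(axis=0)

    p = (1 + (null_counts >= obs_counts[None, :]).sum(axis=0)) / (n_perm + 1)
    sig = grid[p < alpha]
    if len(sig) == 0:
        log.warning("no distance significant at p < %g; using default %d nt",
                    alpha, default)
        return default
    return int(sig.max())


# ---------------------------------------------------------------------------
# context classification


def classify_context(
    clusters: list[ContigCluster],
    genes: list[GeneModel],
    cutoff: int = DEFAULT_CUTOFF,
) -> list[ContextCall]:
    """Assign each intergenic cluster to one context category.

    Orientation is defined in the partner gene's reading direction; the
    nearest annotated transcript boundary within ``cutoff`` picks the
    partner (ties break to the lower-coordinate gene).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    inter = intergenic_clusters(clusters, genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.span.start)

    calls = []
    for cl in inter:
        best = None
        for g in by_chrom.get(cl.chrom, []):
            d = cl.span.gap_to(g.span)
            if d == 0 or d > cutoff:
                continue
            key = (d, g.span.start, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g)
        if best is None:
            continue
        (d, _, _), g = best
        before = cl.span.end <= g.span.start  # cluster left of gene
        upstream = before if g.strand == "+" else not before
        sense = cl.strand == g.strand
        category = ("upstream_" if upstream else "downstream_") + (
            "sense" if sense else "antisense")
        cl.context = category
        calls.append(ContextCall(cl.cluster_id, g.gene_id, category, int(d)))
    calls.sort(key=lambda c: (c.cluster_id, c.partner_gene_id))
    return calls


def correlation_excess(
    calls: list[ContextCall],
    expression,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Observed vs permuted cluster-gene correlation per context category.

    For each of ``n_perm`` permutations the cluster-gene pairing is shuffled
    and a one-sided Wilcoxon rank-sum test asks whether the observed r
    distribution is more positive; reported is the number of permutations
    beaten at p < ``alpha``, plus the BH-significant pair list.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    out = {}
    for category in sorted({c.category for c in calls}):
        sel = [c for c in calls if c.category == category]
        cl_vec, g_vec, kept = [], [], []
        for c in sel:
            va = expression.vector(c.cluster_id)
            vb = expression.vector(c.partner_gene_id)
            if va is None or vb is None:
                continue
            la, lb = log_expr(va), log_expr(vb)
            if la.std() == 0 or lb.std() == 0:
                continue
            cl_vec.append(la)
            g_vec.append(lb)
            kept.append(c)
        if len(kept) < 3:
            continue
        A = np.vstack(cl_vec)
        B = np.vstack(g_vec)
        from .stats import pearson_rows

        obs_r = pearson_rows(A, B)
        n_beaten = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(kept))
            perm_r = pearson_rows(A, B[perm])
            stat = sps.mannwhitneyu(obs_r, perm_r, alternative="greater")
            if stat.pvalue < alpha:
                n_beaten += 1
        # per-pair Pearson p with BH within category
        n = expression.n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            t = obs_r * np.sqrt((n - 2) / np.maximum(1 - obs_r**2, 1e-300))
        pp = 2 * sps.t.sf(np.abs(t), df=n - 2)
        qq = bh_adjust(pp)
        for c, r, q in zip(kept, obs_r, qq):
            c.pearson_r = float(r)
            c.bh_q = float(q)
        sig = [c for c, q, r in zip(kept, qq, obs_r) if q < alpha and r > 0]
        out[category] = {
            "n": len(kept),
            "observed_r": obs_r,
            "n_perm": n_perm,
            "n_beaten": n_beaten,
            "significant": sig,
        }
    return out


# ---------------------------------------------------------------------------
# promoter typing


def _head_to_head(tss_a, span_a, strand_a, tss_b, span_b, strand_b, window) -> bool:
    if abs(tss_a - tss_b) > window:
        return False
    return pair_geometry(span_a, strand_a, span_b, strand_b) == "head_to_head"


def call_promoters(
    genes: list[GeneModel],
    clusters: list[ContigCluster],
    cage: CageTags | None = None,
    bidir_window: int = BIDIR_WINDOW,
    unip_window: int = UNIP_WINDOW,
) -> list[PromoterCall]:
    """Type every gene's promoter as UniP / pcKBiP / lncKBiP / NBiP.

    KBiP takes precedence over NBiP when both partners exist (novelty of the
    partner defines NBiP). A gene qualifying simultaneously as UniP and as a
    bidirectional partner indicates an annotation conflict and raises.
    One call is emitted per promoter: for annotated head-to-head pairs the
    anchor is the protein-coding gene (lower TSS coordinate for pc-pc pairs).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    novel = [c for c in clusters if c.status == "novel"]
    novel_by_chrom: dict[str, list[ContigCluster]] = {}
    for c in novel:
        novel_by_chrom.setdefault(c.chrom, []).append(c)
    all_cl_by_chrom: dict[str, list[ContigCluster]] = {}
    for c in clusters:
        all_cl_by_chrom.setdefault(c.chrom, []).append(c)

    conflicts = []
    assignments: dict[str, tuple] = {}  # gene -> (klass, partner_id, partner_tss)

    for g in genes:
        tss = g.tss
        # annotated head-to-head partner within the bidirectional window
        kbip = None
        for h in by_chrom.get(g.chrom, []):
            if h.gene_id == g.gene_id or h.strand == g.strand:
                continue
            if _head_to_head(tss, g.span, g.strand, h.tss, h.span, h.strand,
                             bidir_window):
                key = (abs(tss - h.tss), h.tss, h.gene_id)
                if kbip is None or key < kbip[0]:
                    kbip = (key, h)
        # novel head-to-head partner
        nbip = None
        for c in novel_by_chrom.get(g.chrom, []):
            if c.strand == g.strand:
                continue
            if _head_to_head(tss, g.span, g.strand, c.five_prime, c.span,
                             c.strand, bidir_window):
                key = (abs(tss - c.five_prime), c.five_prime, c.cluster_id)
                if nbip is None or key < nbip[0]:
                    nbip = (key, c)
        # anything upstream within the UniP window?
        if g.strand == "+":
            up = GenomicInterval(g.chrom, max(0, tss - unip_window), max(1, tss))
        else:
            up = GenomicInterval(g.chrom, tss, tss + unip_window)
        upstream_occupied = any(
            h.gene_id != g.gene_id and h.span.overlaps(up)
            for h in by_chrom.get(g.chrom, [])
        ) or any(c.span.overlaps(up) for c in all_cl_by_chrom.get(g.chrom, []))

        if kbip is not None:
            klass = "pcKBiP" if kbip[1].biotype == "protein_coding" else "lncKBiP"
            if not upstream_occupied and not kbip[1].span.overlaps(up):
                conflicts.append(g.gene_id)
            assignments[g.gene_id] = (klass, kbip[1].gene_id, kbip[1].tss)
        elif nbip is not None:
            assignments[g.gene_id] = ("NBiP", nbip[1].cluster_id, nbip[1].five_prime)
        elif not upstream_occupied:
            assignments[g.gene_id] = ("UniP", None, None)
        # otherwise: unclassified (upstream occupied but no head-to-head pair)

    if conflicts:
        raise ValueError(
            "genes assigned two structural promoter classes (annotation "
            f"conflict): {sorted(set(conflicts))}")

    gene_by_id = {g.gene_id: g for g in genes}
    calls: list[PromoterCall] = []
    seen_pairs: set[tuple[str, str]] = set()
    for g in genes:
        if g.gene_id not in assignments:
            continue
        klass, partner, partner_tss = assignments[g.gene_id]
        if klass in ("pcKBiP", "lncKBiP"):
            # mutual pairs yield one call per promoter, anchored at the
            # protein-coding gene (lower TSS breaks ties); a gene whose
            # partner prefers another gene keeps its own call
            h = gene_by_id[partner]
            partner_assign = assignments.get(partner)
            mutual = (partner_assign is not None
                      and partner_assign[0] in ("pcKBiP", "lncKBiP")
                      and partner_assign[1] == g.gene_id)
            if mutual:
                if (g.biotype == "protein_coding") != (h.biotype == "protein_coding"):
                    anchor = g if g.biotype == "protein_coding" else h
                else:
                    anchor = min(g, h, key=lambda x: (x.tss, x.gene_id))
                pair_key = tuple(sorted([g.gene_id, partner]))
                if pair_key in seen_pairs or anchor.gene_id != g.gene_id:
                    continue
                seen_pairs.add(pair_key)
        tss = g.tss
        if partner_tss is not None:
            mid = (tss + partner_tss) // 2
        else:
            mid = tss
        half = bidir_window // 2
        window = GenomicInterval(g.chrom, max(0, mid - half), mid + half)
        call = PromoterCall(
            anchor_gene_id=g.gene_id, tss=tss, chrom=g.chrom, strand=g.strand,
            partner_id=partner, klass=klass, window=window)
        if cage is not None:
            call.cage_sense = cage.count(g.chrom, window.start, window.end, g.strand)
            call.cage_antisense = cage.count(
                g.chrom, window.start, window.end, "-" if g.strand == "+" else "+")
            call.has_cage = (call.cage_sense + call.cage_antisense) > 0
            call.divergent = call.cage_sense >= 1 and call.cage_antisense >= 1
            call.unidirectional_confirmed = (
                call.cage_sense >= 2 and call.cage_antisense == 0)
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.tss, c.anchor_gene_id))
    n_by_class: dict[str, int] = {}
    for c in calls:
        n_by_class[c.klass] = n_by_class.get(c.klass, 0) + 1
    log.info("promoter calls by class: %s (unclassified genes: %d)",
             n_by_class, len(genes) - len(assignments)
             - sum(1 for c in calls if c.klass in ("pcKBiP", "lncKBiP")))
    return calls


def divergence_enrichment(calls: list[PromoterCall]):
    """Fisher's exact test: divergent fraction at NBiPs vs UniP+KBiP background.

    Only promoters with at least one CAGE tag enter the table.
    """
    nbip = [c for c in calls if c.klass == "NBiP" and c.has_cage]
    back = [c for c in calls if c.klass != "NBiP" and c.has_cage]
    a = sum(c.divergent for c in nbip)
    c_ = sum(c.divergent for c in back)
    return fisher_enrichment("divergent@NBiP", a, len(nbip) - a, c_, len(back) - c_)
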