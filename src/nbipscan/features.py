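"""Sequence and epigenetic features of promoter windows, and class contrasts.

Per promoter window: GC fraction, mean Regulatory Potential, mean phastCons,
H3K4me3 density and profile shape, and DNA methylation. Track-derived
features require > 80% of window bases covered to be valid. The shape
statistic ``shape_s`` is the fraction of summed H3K4me3 signal on the
TSS-upstream half of the window, oriented by the anchor gene's strand, so a
downstream-shifted (asymmetric) profile gives shape_s < 0.5 and a symmetric
profile 0.5.

Class contrasts use two-sided Kolmogorov-Smirnov tests for the sequence
features (GC, RP, conservation) and Mann-Whitney rank-sum tests for
H3K4me3 density and methylation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import SignalTrack
from .promoters import PromoterCall
from .stats import empirical_p

log = logging.getLogger(__name__)

MIN_COVERAGE = 0.8
TRACK_FEATURES = ("rp", "cons", "h3k4me3_density", "methylation")


@dataclass
class PromoterFeatures:
    promoter_id: str
    klass: str
    gc: float = float("nan")
    rp: float = float("nan")
    cons: float = float("nan")
    h3k4me3_density: float = float("nan")
    shape_s: float = float("nan")
    methylation: float = float("nan")
    valid: dict = field(default_factory=dict)


def _fetch_seq(genome, chrom, start, end) -> str:
    rec = genome[chrom]
    start = max(0, start)
    end = min(end, len(rec))
    return rec[start:end].seq.upper()


def compute_features(
    promoters: list[PromoterCall],
    genome,
    tracks: dict[str, SignalTrack] | None = None,
    min_coverage: float = MIN_COVERAGE,
) -> list[PromoterFeatures]:
    """Per-promoter feature vector; absent tracks leave features invalid."""
    tracks = tracks or {}
    track_of = {
        "rp": tracks.get("rp_score"),
        "cons": tracks.get("phastcons"),
        "h3k4me3_density": tracks.get("h3k4me3"),
        "methylation": tracks.get("methylation"),
    }
    out = []
    for p in promoters:
        f = PromoterFeatures(promoter_id=p.anchor_gene_id, klass=p.klass)
        start, end = p.window.start, p.window.end
        chrom_len = len(genome[p.chrom])
        truncated = start < 0 or end > chrom_len
        if truncated:
            log.warning("promoter window for %s truncated at chromosome end",
                        p.anchor_gene_id)
        seq = _fetch_seq(genome, p.chrom, start, end)
        acgt = sum(seq.count(b) for b in "ACGT")
        f.valid["gc"] = acgt / max(1, end - start) > min_coverage
        if acgt:
            f.gc = (seq.count("G") + seq.count("C")) / acgt

        for name, track in track_of.items():
            if track is None:
                f.valid[name] = False
                continue
            mean, cov = track.mean(p.chrom, max(0, start), min(end, chrom_len))
            ok = cov * (min(end, chrom_len) - max(0, start)) / (end - start)
            f.valid[name] = ok > min_coverage
            if f.valid[name]:
                setattr(f, name, mean)

        if track_of["h3k4me3_density"] is not None and f.valid["h3k4me3_density"]:
            vals = track_of["h3k4me3_density"].per_base(
                p.chrom, max(0, start), min(end, chrom_len))
            vals = np.nan_to_num(vals, nan=0.0)
            # split at the anchor TSS projection: window midpoint
            mid = len(vals) // 2
            left, right = vals[:mid].sum(), vals[mid:].sum()
            total = left + right
            if total > 0:
                up = left if p.strand == "+" else right
                f.shape_s = float(up / total)
        out.append(f)
    return out


def features_frame(features: list[PromoterFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        row = dict(promoter_id=f.promoter_id, klass=f.klass, gc=f.gc, rp=f.rp,
                   cons=f.cons, h3k4me3_density=f.h3k4me3_density,
                   shape_s=f.shape_s, methylation=f.methylation)
        for k, v in f.valid.items():
            row[f"valid_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def contrast_classes(
    features: list[PromoterFeatures],
    merge_kbip: bool = True,
) -> pd.DataFrame:
    """All-pairs class contrasts for every feature.

    KS (two-sided) for gc/rp/cons, Mann-Whitney rank-sum for H3K4me3 density
    and methylation; ``direction`` is the sign of the class-median
    difference. ``merge_kbip`` pools pcKBiP and lncKBiP into "KBiP".
    """
    groups: dict[str, dict[str, np.ndarray]] = {}
    for f in features:
        klass = f.klass
        if merge_kbip and klass in ("pcKBiP", "lncKBiP"):
            klass = "KBiP"
        g = groups.setdefault(klass, {})
        for feat in ("gc", "rp", "cons", "h3k4me3_density", "methylation", "shape_s"):
            if f.valid.get(feat if feat != "shape_s" else "h3k4me3_density", False) \
                    and np.isfinite(getattr(f, feat)):
                g.setdefault(feat, []).append(getattr(f, feat))
    for klass in list(groups):
        if not groups[klass]:
            log.info("empty promoter class %s excluded from contrasts", klass)
            del groups[klass]

    rows = []
    tests = {"gc": "ks", "rp": "ks", "cons": "ks",
             "h3k4me3_density": "ranksum", "methylation": "ranksum",
             "shape_s": "ranksum"}
    for feat, test in tests.items():
        for a, b in itertools.combinations(sorted(groups), 2):
            xa = np.asarray(groups[a].get(feat, []), dtype=float)
            xb = np.asarray(groups[b].get(feat, []), dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                continue
            if test == "ks":
                res = sps.ks_2samp(xa, xb)
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            delta = float(np.median(xa) - np.median(xb))
            direction = "none" if (p == 1.0 or delta == 0) else (
                f"{a}>{b}" if delta > 0 else f"{b}>{a}")
            rows.append(dict(feature=feat, class_a=a, class_b=b, test=test,
                             statistic=stat, p=p,
                             mean_a=float(xa.mean()), mean_b=float(xb.mean()),
                             direction=direction, n_a=len(xa), n_b=len(xb)))
    return pd.DataFrame(rows)


def neuron_specificity(
    gene_set: list[str],
    flags: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Neuron/non-neuron ratio of a gene set vs random same-size draws.

    ``flags`` maps every expressed gene to "N" or "nonN"; empirical p is
    (1 + #null >= observed) / (n_perm + 1).
    """
    universe = sorted(flags)
    missing = sorted(set(gene_set) - set(universe))
    if missing:
        raise ValueError(f"genes outside the flagged universe: {missing}")
    rng = np.random.default_rng(seed)
    flag_arr = np.array([flags[g] == "N" for g in universe])
    idx = {g: i for i, g in enumerate(universe)}
    sel = np.array([idx[g] for g in gene_set])

    def stat(indices) -> tuple[float, float]:
        n_n = int(flag_arr[indices].sum())
        n_non = len(indices) - n_n
        ratio = n_n / n_non if n_non else float("inf")
        return ratio, n_n

    obs_ratio, obs_n = stat(sel)
    use_counts = not np.isfinite(obs_ratio)
    null = np.empty(n_perm)
    for k in range(n_perm):
        draw = rng.choice(len(universe), size=len(sel), replace=False)
        r, n_n = stat(draw)
        null[k] = n_n if use_counts else r
    p = empirical_p(obs_n if use_counts else obs_ratio, null, tail="greater")
    return {"ratio": obs_ratio, "n_N": obs_n, "n_nonN": len(sel) - obs_n,
            "p": p, "null": null}


def celltype_enrichment(gene_set: list[str], celltype_table: pd.DataFrame):
    """Fisher's exact enrichment of a gene set per cell type.

    ``celltype_table`` has columns (gene, cell_type); the universe is every
    gene in the table.
    """
    from .stats import fisher_enrichment

    universe = set(celltype_table["gene"])
    inset = set(gene_set) & universe
    rows = []
    for ct, sub in celltype_table.groupby("cell_type"):
        members = set(sub["gene"])
        a = len(inset & members)
        b = len(inset) - a
        c = len(members) - a
        d = len(universe) - len(members) - b
        rows.append(fisher_enrichment(str(ct), a, b, c, d))
    return rows
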