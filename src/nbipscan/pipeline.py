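"""End-to-end orchestration: configuration, staged runs, manifest, recovery.

Stages run in dependency order (elements -> saspairs -> promoters ->
features -> tfbs -> dynamics); every stage draws its randomness from a seed
derived as hash(master seed, stage name), so adding or skipping a stage
never perturbs another stage's random stream. A manifest (config, package
versions, input checksums, per-stage seeds) makes a run reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .antisense import correlation_contrast, expected_junction_links, find_sas_pairs
from .clusters import annotate_status, merge_contigs
from .dynamics import ExpressionMatrix, age_test, cluster_trajectories, read_expression
from .features import compute_features, contrast_classes, features_frame
from .intervals import ContigCluster
from .novel_elements import call_novel_elements, validate_elements
from .promoters import (
    call_promoters,
    classify_context,
    correlation_excess,
    divergence_enrichment,
)
from .tfbs import enrich, read_transfac, scan

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Input paths plus the thresholds the analysis prints."""

    fasta: str = ""
    gtf: str = ""
    contigs: str = ""
    expression: str = ""
    cage: str = ""
    h3k4me3: str = ""
    input_track: str = ""
    methylation: str = ""
    phastcons: str = ""
    rp: str = ""
    peaks: str = ""
    polya: str = ""
    alt_contigs: str = ""
    junctions: str = ""
    pwms: str = ""
    neuron_flags: str = ""

    min_rpkm: float = 0.1
    min_utr_ext: int = 100
    bidir_window: int = 2000
    unip_window: int = 5000
    distance_cutoff: int = 4000
    or_cut: float = 1.3
    q_cut: float = 0.05
    age_p: float = 0.01
    k_clusters: int = 12
    n_perm_context: int = 200
    n_perm_age: int = 1000
    n_subsamples: int = 100
    n_perm_junction: int = 200
    chr_mode: str = "keep"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("min_rpkm", "min_utr_ext", "bidir_window", "unip_window",
                     "distance_cutoff", "or_cut", "q_cut", "age_p", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def attach_cluster_expression(
    clusters: list[ContigCluster], expr: ExpressionMatrix
) -> ExpressionMatrix:
    """Extend the expression matrix with per-cluster rows (mean of members).

    Also sets each cluster's ``mean_rpkm``. Clusters whose members carry no
    expression rows stay absent from the extended matrix.
    """
    extra_ids, extra_rows = [], []
    for cl in clusters:
        rows = [expr.vector(m) for m in cl.members]
        rows = [r for r in rows if r is not None]
        if not rows:
            continue
        v = np.mean(rows, axis=0)
        cl.mean_rpkm = float(v.mean())
        extra_ids.append(cl.cluster_id)
        extra_rows.append(v)
    if not extra_ids:
        return expr
    return ExpressionMatrix(
        expr.ids + extra_ids, expr.samples, expr.ages,
        np.vstack([expr.values, np.vstack(extra_rows)]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _chrom_lens(genome) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def nbip_recovery(calls, truth_promoters: pd.DataFrame) -> dict:
    """Planted-vs-called NBiP recall and false-call rate."""
    planted = set(truth_promoters.loc[
        truth_promoters["klass"] == "NBiP", "anchor_gene"])
    called = {c.anchor_gene_id for c in calls if c.klass == "NBiP"}
    tp = len(planted & called)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "recall": tp / len(planted) if planted else float("nan"),
        "false_call_rate": (len(called) - tp) / len(called) if called else 0.0,
    }


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage whose inputs are present; returns the result bundle."""
    import pyfaidx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": {},
        "inputs": {},
        "versions": _versions(),
        "skipped": [],
    }

    def need(*names) -> bool:
        missing = [n for n in names if not getattr(config, n)
                   or not Path(getattr(config, n)).exists()]
        return missing

    for name in ("fasta", "gtf", "contigs", "expression", "cage", "h3k4me3",
                 "input_track", "methylation", "phastcons", "rp", "peaks",
                 "polya", "alt_contigs", "junctions", "pwms", "neuron_flags"):
        p = getattr(config, name)
        if p and Path(p).exists():
            manifest["inputs"][name] = _sha256(Path(p))

    missing = need("fasta", "gtf", "contigs", "expression")
    if missing:
        raise FileNotFoundError(f"required inputs missing: {missing}")

    genome = pyfaidx.Fasta(config.fasta)
    genes = nio.read_annotation(config.gtf, chr_mode=config.chr_mode)
    contigs = nio.read_bed12(config.contigs, chr_mode=config.chr_mode)
    clusters = annotate_status(merge_contigs(contigs), genes)
    expr = read_expression(config.expression)
    expr_ext = attach_cluster_expression(clusters, expr)
    chrom_lens = _chrom_lens(genome)
    novel_cluster_ids = {c.cluster_id for c in clusters if c.status == "novel"}

    nio.write_bed12(clusters, outdir / "clusters.bed12")
    results["clusters"] = clusters

    # ---- novel elements ---------------------------------------------------
    calls = call_novel_elements(clusters, genes, genome,
                                min_utr_ext=config.min_utr_ext)
    alt = None
    if not need("alt_contigs"):
        alt = annotate_status(
            merge_contigs(nio.read_bed12(config.alt_contigs, config.chr_mode)),
            genes)
    peaks = ([iv for iv, _, _ in nio.read_bed6(config.peaks, config.chr_mode)]
             if not need("peaks") else None)
    polya = ([iv for iv, _, _ in nio.read_bed6(config.polya, config.chr_mode)]
             if not need("polya") else None)
    validate_elements(calls, alt, peaks, polya)
    pd.DataFrame([
        dict(gene_id=c.gene_id, kind=c.element_kind, chrom=c.interval.chrom,
             start=c.interval.start, end=c.interval.end,
             cluster=c.supporting_cluster_id, **c.validated)
        for c in calls
    ]).to_csv(outdir / "novel_elements.tsv", sep="\t", index=False)
    results["elements"] = calls

    # ---- sense/antisense pairs -------------------------------------------
    junctions = (nio.read_junctions(config.junctions, config.chr_mode)
                 if not need("junctions") else None)
    pairs = find_sas_pairs(genes, clusters, junctions, expression=expr_ext,
                           min_mean_rpkm=config.min_rpkm)
    sas_seed = stage_seed(config.seed, "saspairs")
    manifest["stage_seeds"]["saspairs"] = sas_seed
    contrasts = correlation_contrast(pairs, expr_ext, genes,
                                     n_subsamples=config.n_subsamples,
                                     seed=sas_seed)
    results["pairs"] = pairs
    results["pair_contrasts"] = contrasts
    if junctions:
        results["junction_excess"] = expected_junction_links(
            clusters, genes, junctions, chrom_lens,
            n_perm=max(100, config.n_perm_junction), seed=sas_seed)
    pd.DataFrame([
        dict(sense_id=p.sense_id, antisense_id=p.antisense_id,
             geometry=p.geometry, scenario=",".join(sorted(p.scenario)),
             pearson_r=p.pearson_r)
        for p in pairs
    ]).to_csv(outdir / "sas_pairs.tsv", sep="\t", index=False)

    # ---- context & promoters ---------------------------------------------
    ctx_seed = stage_seed(config.seed, "promoters")
    manifest["stage_seeds"]["promoters"] = ctx_seed
    context = classify_context(clusters, genes, cutoff=config.distance_cutoff)
    excess = correlation_excess(context, expr_ext,
                                n_perm=config.n_perm_context, seed=ctx_seed)
    cage = nio.read_cage(config.cage, config.chr_mode) if not need("cage") else None
    promoter_calls = call_promoters(genes, clusters, cage,
                                    bidir_window=config.bidir_window,
                                    unip_window=config.unip_window)
    results["context"] = context
    results["context_excess"] = excess
    results["promoters"] = promoter_calls
    if cage is not None:
        results["divergence"] = divergence_enrichment(promoter_calls)
    pd.DataFrame([
        dict(cluster_id=c.cluster_id, partner=c.partner_gene_id,
             category=c.category, distance=c.distance, pearson_r=c.pearson_r,
             bh_q=c.bh_q)
        for c in context
    ]).to_csv(outdir / "context.tsv", sep="\t", index=False)
    pd.DataFrame([
        dict(anchor=c.anchor_gene_id, klass=c.klass, partner=c.partner_id,
             tss=c.tss, chrom=c.chrom, strand=c.strand,
             cage_sense=c.cage_sense, cage_antisense=c.cage_antisense,
             divergent=c.divergent,
             unidirectional_confirmed=c.unidirectional_confirmed)
        for c in promoter_calls
    ]).to_csv(outdir / "promoters.tsv", sep="\t", index=False)

    # ---- promoter features ------------------------------------------------
    tracks = {}
    for key, attr in (("h3k4me3", "h3k4me3"), ("input", "input_track"),
                      ("methylation", "methylation"),
                      ("phastcons", "phastcons"), ("rp_score", "rp")):
        if not need(attr):
            tracks[key] = nio.read_bedgraph(getattr(config, attr), kind=key,
                                            chr_mode=config.chr_mode)
        else:
            manifest["skipped"].append(f"track:{key}")
    feats = compute_features(promoter_calls, genome, tracks)
    feat_df = features_frame(feats)
    feat_df.to_csv(outdir / "promoter_features.tsv", sep="\t", index=False)
    contrast_df = contrast_classes(feats)
    contrast_df.to_csv(outdir / "feature_contrasts.tsv", sep="\t", index=False)
    results["features"] = feats
    results["feature_contrasts"] = contrast_df

    # ---- TFBS enrichment ---------------------------------------------------
    if not need("pwms"):
        tf_seed = stage_seed(config.seed, "tfbs")
        manifest["stage_seeds"]["tfbs"] = tf_seed
        pwms = read_transfac(config.pwms)
        windows = {}
        for c in promoter_calls:
            if c.klass in ("NBiP", "pcKBiP", "lncKBiP"):
                windows[c.anchor_gene_id] = (
                    c.klass,
                    genome[c.chrom][max(0, c.window.start): c.window.end].seq.upper())
        nbip_hits, kbip_hits = [], []
        n_nbip = sum(1 for k, _ in windows.values() if k == "NBiP")
        n_kbip = len(windows) - n_nbip
        for pid, (klass, seq) in windows.items():
            for pwm in pwms:
                hits = scan(seq, pwm, promoter_id=pid)
                (nbip_hits if klass == "NBiP" else kbip_hits).extend(hits)
        table, enriched_nbip, enriched_kbip = enrich(
            nbip_hits, kbip_hits, n_nbip, n_kbip,
            q_cut=config.q_cut, or_cut=config.or_cut)
        pd.DataFrame([
            dict(matrix_id=r.label, nbip_with=r.a, nbip_without=r.b,
                 kbip_with=r.c, kbip_without=r.d, odds_ratio=r.odds_ratio,
                 p=r.p, q=r.q)
            for r in table
        ]).to_csv(outdir / "tfbs_enrichment.tsv", sep="\t", index=False)
        results["tfbs"] = table
        results["tfbs_enriched_nbip"] = enriched_nbip
        results["tfbs_enriched_kbip"] = enriched_kbip
    else:
        manifest["skipped"].append("tfbs")
        log.warning("PWM library missing; TFBS stage skipped")

    # ---- expression dynamics ----------------------------------------------
    dyn_seed = stage_seed(config.seed, "dynamics")
    manifest["stage_seeds"]["dynamics"] = dyn_seed
    age = age_test(expr_ext, n_perm=config.n_perm_age, seed=dyn_seed,
                   p_cut=config.age_p)
    n_sig = sum(r.significant for r in age)
    if n_sig >= config.k_clusters:
        labels, ctests = cluster_trajectories(
            age, expr_ext, novel_cluster_ids
            | {t for t in expr_ext.ids if t.startswith(("nv_", "xt_"))},
            k=config.k_clusters, seed=dyn_seed)
        results["trajectory_clusters"] = (labels, ctests)
    pd.DataFrame([
        dict(id=r.transcript_id, best_degree=r.best_degree, f_p=r.f_p,
             perm_p=r.perm_p, q=r.q, cluster=r.cluster)
        for r in age
    ]).to_csv(outdir / "age_test.tsv", sep="\t", index=False)
    results["age"] = age

    # ---- neuron specificity -----------------------------------------------
    if not need("neuron_flags"):
        flags = dict(pd.read_csv(config.neuron_flags, sep="\t").values)
        nbip_genes = [c.anchor_gene_id for c in promoter_calls
                      if c.klass == "NBiP" and c.anchor_gene_id in flags]
        if nbip_genes:
            from .features import neuron_specificity

            ns_seed = stage_seed(config.seed, "neuron")
            manifest["stage_seeds"]["neuron"] = ns_seed
            results["neuron_specificity"] = neuron_specificity(
                nbip_genes, flags, n_perm=1000, seed=ns_seed)

    # ---- truth recovery (synthetic runs) -----------------------------------
    truth_dir = Path(config.gtf).parent / "truth"
    if (truth_dir / "promoters.tsv").exists():
        truth = pd.read_csv(truth_dir / "promoters.tsv", sep="\t")
        results["recovery"] = nbip_recovery(promoter_calls, truth)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(results["recovery"], fh, indent=1)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "nbipscan": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
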