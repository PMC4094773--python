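"""Context classification, distance cutoff, correlation excess, promoter typing."""

import numpy as np
import pandas as pd
import pytest

from nbipscan import (
    CageTags,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    annotate_status,
    call_promoters,
    classify_context,
    correlation_excess,
    divergence_enrichment,
    estimate_distance_cutoff,
    merge_contigs,
)
from nbipscan.io import Contig


def gi(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def gene(gid, start, end, strand, chrom="chr1", biotype="protein_coding"):
    return GeneModel(gid, biotype, strand, [[gi(chrom, start, end, strand)]])


def cluster(name, start, end, strand, chrom="chr1"):
    return Contig(name, gi(chrom, start, end, strand), strand,
                  [gi(chrom, start, end, strand)])


def build(contigs, genes):
    cl = merge_contigs(contigs)
    annotate_status(cl, genes)
    return cl


class TestClassifyContext:
    def test_upstream_antisense(self):
        g = gene("g", 10000, 12000, "+")
        cl = build([cluster("c", 8500, 9500, "-")], [g])
        calls = classify_context(cl, [g], cutoff=4000)
        assert len(calls) == 1
        assert calls[0].category == "upstream_antisense"
        assert calls[0].distance == 500

    def test_downstream_sense(self):
        g = gene("g", 10000, 20000, "+")
        cl = build([cluster("c", 21000, 22000, "+")], [g])
        calls = classify_context(cl, [g], cutoff=4000)
        assert calls[0].category == "downstream_sense"

    def test_orientation_follows_partner_strand(self):
        g = gene("g", 10000, 20000, "-")
        cl = build([cluster("c", 21000, 22000, "+")], [g])
        assert classify_context(cl, [g], cutoff=4000)[0].category == \
            "upstream_antisense"

    def test_beyond_cutoff_no_call(self):
        g = gene("g", 10000, 20000, "+")
        cl = build([cluster("c", 24001, 25000, "+")], [g])
        assert classify_context(cl, [g], cutoff=4000) == []
        cl = build([cluster("c", 24000, 25000, "+")], [g])
        assert len(classify_context(cl, [g], cutoff=4000)) == 1

    def test_gene_overlapping_cluster_excluded(self):
        g = gene("g", 10000, 20000, "+")
        cl = build([cluster("c", 19000, 21000, "-")], [g])
        assert classify_context(cl, [g], cutoff=4000) == []

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            classify_context([], [], cutoff=0)


class TestDistanceCutoff:
    def _fixture(self, d, n=20, spacing=50000):
        genes, contigs = [], []
        for i in range(n):
            base = 20000 + i * spacing
            genes.append(gene(f"g{i}", base, base + 2000, "+"))
            contigs.append(cluster(f"c{i}", base - d - 1000, base - d, "-"))
        cl = build(contigs, genes)
        return cl, genes, {"chr1": 20000 + n * spacing}

    def test_planted_at_1000_gives_cutoff_at_least_1000(self):
        cl, genes, lens = self._fixture(1000)
        cut = estimate_distance_cutoff(cl, genes, lens, n_perm=200, seed=0)
        assert cut >= 1000

    def test_uniformly_far_clusters_fall_back_to_default(self, caplog):
        genes = [gene(f"g{i}", 20000 + i * 100000, 22000 + i * 100000, "+")
                 for i in range(12)]
        contigs = [cluster(f"c{i}", 70000 + i * 100000, 71000 + i * 100000, "-")
                   for i in range(12)]
        cl = build(contigs, genes)
        with caplog.at_level("WARNING"):
            cut = estimate_distance_cutoff(cl, genes, {"chr1": 1300000},
                                           n_perm=100, seed=0, max_distance=5000)
        assert cut == 4000
        assert any("default" in r.message for r in caplog.records)

    def test_too_few_clusters_raises(self):
        cl, genes, lens = self._fixture(1000, n=5)
        with pytest.raises(ValueError, match="fixed"):
            estimate_distance_cutoff(cl, genes, lens)

    def test_stable_under_more_permutations(self):
        cl, genes, lens = self._fixture(1500)
        a = estimate_distance_cutoff(cl, genes, lens, n_perm=100, seed=3)
        b = estimate_distance_cutoff(cl, genes, lens, n_perm=200, seed=3)
        assert a == b


class TestCorrelationExcess:
    def _calls_expr(self, r, n_pairs=25, n_samples=14, seed=0):
        rng = np.random.default_rng(seed)
        genes, contigs, ids, vals = [], [], [], []
        z = rng.standard_normal((n_pairs, n_samples))
        for i in range(n_pairs):
            base = 20000 + i * 30000
            genes.append(gene(f"g{i}", base, base + 2000, "+"))
            contigs.append(cluster(f"c{i}", base - 1500, base - 500, "-"))
            a = np.sqrt(abs(r))
            e1, e2 = rng.standard_normal(n_samples), rng.standard_normal(n_samples)
            vals.append(2 ** (3 + a * z[i] + np.sqrt(1 - a**2) * e1))
            ids.append(f"g{i}")
        cl = build(contigs, genes)
        calls = classify_context(cl, genes, cutoff=4000)
        for c, i in zip(calls, range(n_pairs)):
            a = np.sqrt(abs(r))
            e2 = rng.standard_normal(n_samples)
            ids.append(c.cluster_id)
            vals.append(2 ** (3 + np.sign(r or 1) * a * z[i]
                              + np.sqrt(1 - a**2) * e2))
        expr = ExpressionMatrix(ids, [f"s{k}" for k in range(n_samples)],
                                np.geomspace(2, 35000, n_samples), np.array(vals))
        return calls, expr

    def test_planted_correlation_beats_all_permutations(self):
        calls, expr = self._calls_expr(0.8)
        out = correlation_excess(calls, expr, n_perm=100, seed=1)
        res = out["upstream_antisense"]
        assert res["n_beaten"] == res["n_perm"]
        assert len(res["significant"]) >= 0.8 * res["n"]

    def test_single_call_bh_list_short(self):
        calls, expr = self._calls_expr(0.9, n_pairs=3)
        out = correlation_excess(calls, expr, n_perm=10, seed=1)
        assert len(out["upstream_antisense"]["significant"]) <= 3

    def test_n_perm_validation(self):
        with pytest.raises(ValueError):
            correlation_excess([], None, n_perm=1)


class TestCallPromoters:
    def test_nbip_geometry(self):
        g = gene("g", 10000, 12000, "+")
        cl = build([cluster("c", 8500, 9400, "-")], [g])
        calls = call_promoters([g], cl)
        assert len(calls) == 1
        assert calls[0].klass == "NBiP"
        assert calls[0].partner_id == cl[0].cluster_id

    def test_lnc_partner_gives_lnckbip(self):
        g = gene("g", 10000, 12000, "+")
        lnc = gene("l", 7500, 8500, "-", biotype="lncRNA")
        calls = call_promoters([g, lnc], [])
        assert [c.klass for c in calls] == ["lncKBiP"]
        assert calls[0].anchor_gene_id == "g"

    def test_unip_with_cage_confirmation(self):
        g = gene("g", 10000, 12000, "+")
        cage = CageTags.from_records([("chr1", 9990, "+", 2)])
        calls = call_promoters([g], [], cage)
        assert calls[0].klass == "UniP"
        assert calls[0].unidirectional_confirmed
        assert not calls[0].divergent

    def test_divergent_flag_needs_tag_on_each_strand(self):
        g = gene("g", 10000, 12000, "+")
        cl = build([cluster("c", 8500, 9400, "-")], [g])
        cage = CageTags.from_records([("chr1", 9990, "+", 2),
                                      ("chr1", 9410, "-", 1)])
        calls = call_promoters([g], cl, cage)
        assert calls[0].divergent

    def test_transcript_upstream_blocks_unip(self):
        g = gene("g", 10000, 12000, "+")
        other = gene("o", 5500, 6500, "+")
        calls = call_promoters([g, other], [])
        klass = {c.anchor_gene_id: c.klass for c in calls}
        assert "g" not in klass  # unclassified: occupied upstream, no h2h pair
        assert klass["o"] == "UniP"

    def test_kbip_precedence_over_nbip(self):
        g = gene("g", 10000, 12000, "+")
        partner = gene("p", 7500, 9000, "-")
        cl = build([cluster("c", 8500, 9400, "-")], [g, partner])
        calls = call_promoters([g, partner], cl)
        assert [c.klass for c in calls] == ["pcKBiP"]
        assert {calls[0].anchor_gene_id, calls[0].partner_id} == {"g", "p"}

    def test_window_cutoff(self):
        g = gene("g", 10000, 12000, "+")
        cl = build([cluster("c", 7000, 7999, "-")], [g])  # TSS gap 2001
        calls = call_promoters([g], cl)
        assert not [c for c in calls if c.klass == "NBiP"]
        cl = build([cluster("c", 7000, 8000, "-")], [g])  # TSS gap 2000
        calls = call_promoters([g], cl)
        assert calls[0].klass == "NBiP"

    def test_conflict_raises(self):
        # head-to-head partner entirely at/after the TSS: the gene also
        # qualifies as UniP (empty upstream window)
        g = gene("g", 10000, 20000, "+")
        partner = gene("p", 10000, 11000, "-")
        with pytest.raises(ValueError, match="conflict"):
            call_promoters([g, partner], [])


class TestOnFixture:
    def test_classes_mutually_exclusive_and_counted(self, pipeline_results, sim_dir):
        results, _ = pipeline_results
        calls = results["promoters"]
        anchors = [c.anchor_gene_id for c in calls]
        assert len(anchors) == len(set(anchors))
        truth = pd.read_csv(sim_dir / "truth/promoters.tsv", sep="\t")
        truth_k = dict(zip(truth["anchor_gene"], truth["klass"]))
        for c in calls:
            if c.anchor_gene_id in truth_k:
                assert c.klass == truth_k[c.anchor_gene_id], c.anchor_gene_id

    def test_divergence_enrichment_direction(self, pipeline_results):
        results, _ = pipeline_results
        enr = results["divergence"]
        assert enr.odds_ratio > 1.3
        assert enr.p < 1e-4

    def test_context_truth_recovered(self, pipeline_results, sim_dir):
        results, _ = pipeline_results
        truth = pd.read_csv(sim_dir / "truth/context.tsv", sep="\t")
        byid = {}
        for call in results["context"]:
            cl = next(c for c in results["clusters"]
                      if c.cluster_id == call.cluster_id)
            for m in cl.members:
                byid[m] = call
        hits = sum(
            byid[r["contig"]].category == r["category"]
            and byid[r["contig"]].partner_gene_id == r["gene"]
            for _, r in truth.iterrows() if r["contig"] in byid)
        assert hits >= 0.95 * len(truth)

    def test_upstream_antisense_excess_on_fixture(self, pipeline_results):
        results, _ = pipeline_results
        res = results["context_excess"]["upstream_antisense"]
        assert res["n_beaten"] == res["n_perm"]
        da = results["context_excess"]["downstream_antisense"]
        assert da["n_beaten"] <= 0.25 * da["n_perm"]


def test_divergence_enrichment_table():
    from nbipscan.promoters import PromoterCall

    def call(klass, divergent, has_cage=True):
        return PromoterCall("g", 0, "chr1", "+", None, klass,
                            gi("chr1", 0, 10), has_cage=has_cage,
                            divergent=divergent)

    calls = ([call("NBiP", True)] * 8 + [call("NBiP", False)] * 2
             + [call("UniP", False)] * 10 + [call("UniP", True)] * 0
             + [call("UniP", False, has_cage=False)] * 5)
    enr = divergence_enrichment(calls)
    assert (enr.a, enr.b, enr.c, enr.d) == (8, 2, 0, 10)
    assert enr.p < 0.01
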