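"""Core data model: format round trips, contig merging, known/novel status."""

import numpy as np
import pytest

from nbipscan import GenomicInterval, annotate_status, merge_contigs
from nbipscan import io as nio
from nbipscan.io import Contig


def gi(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def contig(name, chrom, start, end, strand, blocks=None):
    blocks = blocks or [(start, end)]
    return Contig(name, gi(chrom, start, end, strand), strand,
                  [gi(chrom, a, b, strand) for a, b in blocks])


class TestGtf:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\t.\texon\t101\t200\t.\t+\t.\t'
                     'gene_id "g1"; transcript_id "t1";\n')
        genes = nio.read_annotation(p)
        assert len(genes) == 1
        e = genes[0].transcripts[0][0]
        assert (e.start, e.end, e.strand) == (100, 200, "+")

    def test_two_transcripts_one_gene(self, tmp_path):
        p = tmp_path / "a.gtf"
        lines = [
            'chr1\t.\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
            'chr1\t.\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
            'chr1\t.\texon\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
        ]
        p.write_text("\n".join(lines) + "\n")
        genes = nio.read_annotation(p)
        assert len(genes) == 1
        assert len(genes[0].transcripts) == 2
        assert genes[0].span.start == 0 and genes[0].span.end == 300

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert nio.read_annotation(p) == []
        assert any("empty" in r.message or "no exon" in r.message
                   for r in caplog.records)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\t.\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t";\n'
                     "chr1\tbroken\n")
        with pytest.raises(ValueError, match="line 2"):
            nio.read_annotation(p)

    def test_unknown_strand_raises(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\t.\texon\t1\t100\t.\t*\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(ValueError, match="strand"):
            nio.read_annotation(p)

    def test_round_trip_bit_exact(self, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        lines = [
            'chr1\tnbipscan\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1"; gene_biotype "protein_coding";',
            'chr1\tnbipscan\texon\t401\t500\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1"; gene_biotype "protein_coding";',
            'chr2\tnbipscan\texon\t51\t150\t.\t-\t.\tgene_id "g2"; transcript_id "g2.t1"; gene_biotype "lncRNA";',
        ]
        p1.write_text("\n".join(lines) + "\n")
        genes = nio.read_annotation(p1)
        nio.write_annotation(genes, p2)
        assert nio.read_annotation(p2) == genes
        assert p2.read_text() == p1.read_text()


class TestBedRoundTrips:
    def test_bed12(self, tmp_path):
        cs = [
            contig("a", "chr1", 0, 1000, "+", [(0, 200), (800, 1000)]),
            contig("b", "chr1", 500, 900, "-", [(500, 900)]),
        ]
        p = tmp_path / "x.bed12"
        nio.write_bed12(cs, p)
        back = nio.read_bed12(p)
        assert [(c.name, c.span, c.blocks) for c in back] == \
            [(c.name, c.span, c.blocks) for c in sorted(cs, key=lambda c: c.span.start)]
        p2 = tmp_path / "y.bed12"
        nio.write_bed12(back, p2)
        assert p2.read_text() == p.read_text()

    def test_bedgraph(self, tmp_path):
        from nbipscan import SignalTrack

        t = SignalTrack("h3k4me3")
        t.add_segments("chr1", [0, 100], [100, 150], [1.5, 2.0])
        t.finalize()
        p = tmp_path / "t.bg"
        nio.write_bedgraph(t, p)
        back = nio.read_bedgraph(p, kind="h3k4me3")
        s, e, v = back.segments("chr1")
        assert list(s) == [0, 100] and list(e) == [100, 150]
        assert list(v) == [1.5, 2.0]

    def test_cage_counts_validated(self, tmp_path):
        p = tmp_path / "cage.bed"
        p.write_text("chr1\t10\t11\ttag\t0\t+\n")
        with pytest.raises(ValueError, match=">= 1"):
            nio.read_cage(p)


class TestMergeContigs:
    def test_same_strand_overlap_merges(self):
        cl = merge_contigs([contig("a", "chr1", 0, 100, "+"),
                            contig("b", "chr1", 50, 150, "+")])
        assert len(cl) == 1
        assert (cl[0].span.start, cl[0].span.end) == (0, 150)

    def test_opposite_strands_stay_separate(self):
        cl = merge_contigs([contig("a", "chr1", 0, 100, "+"),
                            contig("b", "chr1", 50, 150, "-")])
        assert len(cl) == 2

    def test_transitive_closure_against_union_find(self, rng):
        """Sweep merging equals a brute-force union-find over pairwise overlaps."""
        for _ in range(50):
            n = int(rng.integers(3, 30))
            cs = []
            for i in range(n):
                s = int(rng.integers(0, 500))
                e = s + int(rng.integers(1, 120))
                strand = "+" if rng.random() < 0.5 else "-"
                cs.append(contig(f"c{i}", "chr1", s, e, strand))
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = cs[i], cs[j]
                    if a.strand == b.strand and a.span.overlaps(b.span):
                        parent[find(i)] = find(j)
            expected = {}
            for i in range(n):
                expected.setdefault(find(i), set()).add(cs[i].name)
            got = {frozenset(cl.members) for cl in merge_contigs(cs)}
            assert got == {frozenset(v) for v in expected.values()}

    def test_order_independence(self, rng):
        cs = [contig(f"c{i}", "chr1", int(rng.integers(0, 400)),
                     int(rng.integers(401, 800)), "+") for i in range(20)]
        a = merge_contigs(cs)
        perm = list(rng.permutation(len(cs)))
        b = merge_contigs([cs[i] for i in perm])
        assert [(c.cluster_id, c.span, c.members) for c in a] == \
            [(c.cluster_id, c.span, c.members) for c in b]

    def test_block_outside_span_raises(self):
        with pytest.raises(ValueError, match="outside span"):
            from nbipscan import ContigCluster
            ContigCluster("x", gi("chr1", 0, 100), "+", [gi("chr1", 50, 150)])


class TestAnnotateStatus:
    def _gene(self, chrom, start, end, strand, gid="g"):
        from nbipscan import GeneModel
        return GeneModel(gid, "protein_coding", strand,
                         [[gi(chrom, start, end, strand)]])

    def test_inside_gene_same_strand_known(self):
        cl = merge_contigs([contig("a", "chr1", 120, 180, "+")])
        annotate_status(cl, [self._gene("chr1", 100, 200, "+")])
        assert cl[0].status == "known"

    def test_antisense_only_is_novel(self):
        cl = merge_contigs([contig("a", "chr1", 120, 180, "-")])
        annotate_status(cl, [self._gene("chr1", 100, 200, "+")])
        assert cl[0].status == "novel"

    def test_single_nucleotide_overlap_known(self):
        cl = merge_contigs([contig("a", "chr1", 199, 300, "+")])
        annotate_status(cl, [self._gene("chr1", 100, 200, "+")])
        assert cl[0].status == "known"
        cl = merge_contigs([contig("a", "chr1", 200, 300, "+")])
        annotate_status(cl, [self._gene("chr1", 100, 200, "+")])
        assert cl[0].status == "novel"

    def test_missing_chromosome_in_seqdict(self):
        cl = merge_contigs([contig("a", "chrX", 0, 10, "+")])
        with pytest.raises(ValueError, match="chrX"):
            annotate_status(cl, [], seqdict={"chr1"})


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, "x")
    assert len(gi("chr1", 0, 10)) == 10
    assert gi("chr1", 0, 10).gap_to(gi("chr1", 15, 20)) == 5
    assert gi("chr1", 0, 10).gap_to(gi("chr1", 5, 20)) == 0


def test_signal_track_per_base_nan_outside_segments():
    from nbipscan import SignalTrack

    t = SignalTrack()
    t.add_segments("chr1", [10], [20], [3.0])
    t.finalize()
    v = t.per_base("chr1", 5, 25)
    assert np.isnan(v[:5]).all() and np.isnan(v[15:]).all()
    assert (v[5:15] == 3.0).all()
    mean, cov = t.mean("chr1", 5, 25)
    assert mean == 3.0 and cov == 0.5
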