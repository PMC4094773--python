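"""PWM scoring, dinucleotide shuffling, enrichment, profiles."""

import numpy as np
import pytest

from nbipscan import (
    PWM,
    density_profile,
    dinucleotide_shuffle,
    enrich,
    read_transfac,
    scan,
    tf_target_correlation,
)
from nbipscan.dynamics import ExpressionMatrix
from nbipscan.tfbs import TfbsHit


def sharp_pwm(consensus, strength=12, mid="M1"):
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = strength
    return PWM(mid, counts)


def dinuc_counts(seq):
    from collections import Counter
    return Counter(zip(seq, seq[1:]))


class TestScoring:
    def test_single_position_consensus_scores_one(self):
        pwm = PWM("m", np.array([[1.0, 0, 0, 0]]))
        hits = scan("A", pwm)
        assert any(h.mss == pytest.approx(1.0) for h in hits)

    def test_consensus_exactly_one_anticonsensus_zero(self):
        pwm = sharp_pwm("ACGTACGT")
        m_cons, _ = _best_scores(pwm.consensus, pwm)
        m_anti, _ = _best_scores(pwm.anti_consensus, pwm, best=False)
        assert m_cons == pytest.approx(1.0, abs=1e-12)
        assert m_anti == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PWM("m", np.ones((6, 4)))

    def test_reverse_complement_mirror(self, rng):
        pwm = sharp_pwm("GATTACA")
        seq = "".join(rng.choice(list("ACGT"), 200))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan(seq, pwm)
        rev = scan(rc, pwm)
        L = len(pwm)
        mirrored = sorted(
            (len(seq) - h.position - L, {"+": "-", "-": "+"}[h.strand],
             round(h.mss, 12))
            for h in rev)
        assert sorted((h.position, h.strand, round(h.mss, 12)) for h in fwd) \
            == mirrored

    def test_column_scaling_invariance(self, rng):
        counts = rng.random((8, 4)) * 10 + 0.5
        a = PWM("a", counts.copy())
        scaled = counts.copy()
        scaled[3] *= 17.0
        b = PWM("b", scaled)
        seq = "".join(rng.choice(list("ACGT"), 100))
        ha = [(h.position, h.strand, h.mss) for h in scan(seq, a)]
        hb = [(h.position, h.strand, h.mss) for h in scan(seq, b)]
        assert ha == pytest.approx(hb)

    def test_windows_with_n_skipped(self):
        pwm = sharp_pwm("ACGT")
        assert scan("NNNN", pwm) == []

    def test_transfac_reader_on_fixture(self, sim_dir):
        pwms = read_transfac(sim_dir / "matrices.dat")
        assert len(pwms) == 10
        assert pwms[0].matrix_id == "M00001_SYNTF1"
        assert all(len(p) == 12 for p in pwms)


def _best_scores(seq, pwm, best=True):
    from nbipscan.tfbs import _scan_strand, encode

    mss, css = _scan_strand(encode(seq), pwm)
    i = np.nanargmax(mss) if best else np.nanargmin(mss)
    return float(mss[i]), float(css[i])


class TestShuffle:
    def test_homopolymer_identity(self):
        assert dinucleotide_shuffle("AAAA", 0) == "AAAA"

    def test_acgt_counts_preserved(self):
        out = dinucleotide_shuffle("ACGT", 1)
        assert dinuc_counts(out) == dinuc_counts("ACGT")
        assert out[0] == "A" and out[-1] == "T"

    @pytest.mark.parametrize("length", [2, 10, 100, 500])
    def test_counts_preserved_across_lengths(self, length, rng):
        seq = "".join(rng.choice(list("ACGT"), length))
        for trial in range(5):
            out = dinucleotide_shuffle(seq, int(rng.integers(1 << 30)))
            assert dinuc_counts(out) == dinuc_counts(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_deterministic_under_seed(self):
        seq = "ACGTACGGTTACGATC" * 5
        assert dinucleotide_shuffle(seq, 42) == dinucleotide_shuffle(seq, 42)
        assert dinucleotide_shuffle(seq, 42) != dinucleotide_shuffle(seq, 43)

    def test_randomizes_order(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        outs = {dinucleotide_shuffle(seq, s) for s in range(5)}
        assert len(outs) > 1


class TestEnrich:
    def _hits(self, mid, n, prefix):
        return [TfbsHit(mid, f"{prefix}{i}", 0, "+", 1.0, 1.0) for i in range(n)]

    def test_odds_ratio_exact_arithmetic(self):
        res, _, _ = enrich(self._hits("M1", 30, "n"), self._hits("M1", 10, "k"),
                           100, 100)
        assert res[0].odds_ratio == pytest.approx((30 * 90) / (70 * 10))

    def test_identical_proportions_not_enriched(self):
        res, nb, kb = enrich(self._hits("M1", 20, "n"), self._hits("M1", 20, "k"),
                             100, 100)
        assert res[0].odds_ratio == pytest.approx(1.0)
        assert nb == [] and kb == []

    def test_odds_ratio_filter_blocks_weak_effects(self):
        # massive counts: tiny p but OR 1.25 < 1.3
        res, nb, _ = enrich(self._hits("M1", 500, "n"), self._hits("M1", 444, "k"),
                            1000, 1000)
        assert res[0].q < 0.05
        assert 1.2 < res[0].odds_ratio < 1.3
        assert nb == []

    def test_zero_cell_defined(self):
        res, nb, _ = enrich(self._hits("M1", 10, "n"), [], 40, 40)
        assert np.isinf(res[0].odds_ratio)
        assert res[0].p < 0.01
        assert nb and nb[0].label == "M1"


class TestDensityProfile:
    def test_planted_center_flagged(self, rng):
        pwm = sharp_pwm("GCGCATAT")
        seqs = []
        for i in range(30):
            s = list("".join(rng.choice(list("ACGT"), 200)))
            if i < 24:
                s[96:104] = "GCGCATAT"
            seqs.append("".join(s))
        res = density_profile(seqs, pwm, n_shuffles=60, seed=1)
        assert res["central_peak"]

    def test_no_planting_inside_band(self, rng):
        pwm = sharp_pwm("GCGCATAT")
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(20)]
        res = density_profile(seqs, pwm, n_shuffles=60, seed=1)
        frac_in = (res["observed"] <= res["band"][1]).mean()
        assert frac_in >= 0.95

    def test_zero_shuffles_profile_only(self, rng):
        pwm = sharp_pwm("GCGCATAT")
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
        res = density_profile(seqs, pwm, n_shuffles=0)
        assert res["band"] is None and not res["central_peak"]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            density_profile(["ACGTACGT", "ACGT"], sharp_pwm("ACGT"), 0)


class TestTfTargetCorrelation:
    def _expr(self, values, ids=None):
        values = np.asarray(values)
        ids = ids or [f"t{i}" for i in range(len(values))]
        return ExpressionMatrix(ids, [f"s{i}" for i in range(values.shape[1])],
                                np.linspace(1, 50, values.shape[1]), values)

    def test_identical_targets_give_r_one_minimal_p(self, rng):
        v = rng.random(10) * 4 + 1
        mat = np.vstack([v, v, v] + [rng.random(10) * 4 + 1 for _ in range(30)])
        expr = self._expr(mat)
        res = tf_target_correlation(v, {"TF": ["t0", "t1", "t2"]}, expr,
                                    n_perm=100, seed=1)
        assert res["TF"]["mean_r"] == pytest.approx(1.0)
        assert res["TF"]["p"] <= 5 / 101

    def test_random_targets_p_moderate(self, rng):
        mat = rng.random((40, 12)) * 4
        expr = self._expr(mat)
        ps = []
        for k in range(20):
            tf = rng.random(12) * 4
            res = tf_target_correlation(
                tf, {"TF": [f"t{i}" for i in rng.choice(40, 5, replace=False)]},
                expr, n_perm=60, seed=k)
            ps.append(res["TF"]["p"])
        assert 0.2 < np.mean(ps) < 0.8

    def test_zero_variance_tf_raises(self, rng):
        expr = self._expr(rng.random((5, 8)))
        with pytest.raises(ValueError, match="zero-variance"):
            tf_target_correlation(np.ones(8), {"TF": ["t0"]}, expr, n_perm=10)

    def test_too_few_samples_raises(self, rng):
        expr = self._expr(rng.random((5, 2)))
        with pytest.raises(ValueError, match="samples"):
            tf_target_correlation(np.ones(2), {"TF": ["t0"]}, expr, n_perm=10)

    def test_planted_tf_program_on_fixture(self, sim_dir):
        import pandas as pd

        from nbipscan.dynamics import read_expression

        expr = read_expression(sim_dir / "expression.tsv")
        truth = pd.read_csv(sim_dir / "truth/promoters.tsv", sep="\t")
        nbip = truth[truth["klass"] == "NBiP"]
        targets = list(nbip["partner"].iloc[: len(nbip) // 2])
        res = tf_target_correlation(
            expr.vector("g_tf0001"), {"SYNTF1": targets}, expr,
            n_perm=200, seed=2)
        assert res["SYNTF1"]["mean_r"] > 0.5
        assert res["SYNTF1"]["p"] == pytest.approx(1 / 201)
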