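"""Expression dynamics: age-trajectory testing, trajectory clustering,
tissue specificity, subcellular localization, strandedness QC.

Expression is RPKM; all model fitting operates on log2(RPKM + 0.1) against
log2(age in days + 1). The age test fits polynomials of increasing degree
(selected by incremental F-tests, capped at 3) and compares against the
intercept-only model; significance is calibrated by permuting sample age
labels, and the false discovery rate at the permutation-p cutoff is the mean
permuted positive count over the observed positive count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .stats import bh_adjust, fisher_enrichment, log_expr

log = logging.getLogger(__name__)

MAX_DEGREE = 3
AGE_P_CUT = 0.01


@dataclass
class ExpressionMatrix:
    """Transcripts x samples RPKM with per-sample ages (days)."""

    ids: list[str]
    samples: list[str]
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.samples)):
            raise ValueError("expression matrix shape mismatch")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("expression values must be finite and >= 0")
        if len(self.ages) != len(self.samples) or np.any(self.ages <= 0):
            raise ValueError("ages must be positive and aligned to samples")
        self._index = {t: i for i, t in enumerate(self.ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def vector(self, tid: str) -> np.ndarray | None:
        i = self._index.get(tid)
        return None if i is None else self.values[i]

    def mean_of(self, tid: str) -> float | None:
        v = self.vector(tid)
        return None if v is None else float(v.mean())

    def subset(self, ids: list[str]) -> "ExpressionMatrix":
        rows = [self._index[t] for t in ids]
        return ExpressionMatrix(list(ids), self.samples, self.ages,
                                self.values[rows])


def read_expression(path) -> ExpressionMatrix:
    """Delimited table; header = sample ids, first data row = ages (days)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index[0] != "age_days":
        raise ValueError(f"{path}: first row must carry sample ages ('age_days')")
    ages = df.iloc[0].to_numpy(dtype=float)
    body = df.iloc[1:]
    return ExpressionMatrix(list(body.index), list(df.columns), ages,
                            body.to_numpy(dtype=float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(expr.samples) + "\n")
        fh.write("age_days\t" + "\t".join(f"{a:.6g}" for a in expr.ages) + "\n")
        for tid, row in zip(expr.ids, expr.values):
            fh.write(tid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class AgeTestResult:
    transcript_id: str
    best_degree: int
    f_p: float
    perm_p: float
    q: float
    cluster: int | None = None

    @property
    def significant(self) -> bool:
        return self.perm_p < AGE_P_CUT


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def _fit_rss(Y: np.ndarray, x: np.ndarray, max_degree: int) -> np.ndarray:
    """(max_degree+1, n_transcripts) residual sums of squares, degree 0.."""
    n = len(x)
    out = np.empty((max_degree + 1, Y.shape[0]))
    out[0] = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for d in range(1, max_degree + 1):
        X = _design(x, d)
        Q, _ = np.linalg.qr(X)
        resid = Y - (Y @ Q) @ Q.T
        out[d] = (resid**2).sum(axis=1)
    return out


def _select_and_test(rss: np.ndarray, n: int, max_degree: int):
    """Degree selection + F-test p vs intercept-only, vectorized.

    Degree starts at 1 and steps up while the incremental F-test against the
    previous degree has p < 0.05 (capped at ``max_degree``).
    """
    m = rss.shape[1]
    degree = np.ones(m, dtype=int)
    active = np.ones(m, dtype=bool)
    for d in range(2, max_degree + 1):
        prev = rss[d - 1]
        cur = np.maximum(rss[d], 1e-300)
        df2 = n - (d + 1)
        if df2 <= 0:
            break
        F = (prev - cur) / (cur / df2)
        p_inc = sps.f.sf(F, 1, df2)
        step = active & (p_inc < 0.05)
        degree[step] = d
        active = step
    rss_best = rss[degree, np.arange(m)]
    df2 = n - (degree + 1)
    F = ((rss[0] - rss_best) / degree) / np.maximum(rss_best, 1e-300) * df2
    f_p = sps.f.sf(F, degree, df2)
    # constant expression vectors: rss0 == 0 -> not significant
    flat = rss[0] <= 1e-12
    f_p[flat] = 1.0
    return degree, f_p


def age_test(
    expr: ExpressionMatrix,
    max_degree: int = MAX_DEGREE,
    n_perm: int = 1000,
    seed: int = 0,
    p_cut: float = AGE_P_CUT,
) -> list[AgeTestResult]:
    """Polynomial age-trajectory test with permutation calibration.

    ``perm_p`` is (1 + #permutations with parametric p as small) / (n+1) per
    transcript; the FDR at ``p_cut`` is the mean permuted positive count over
    the observed positive count.
    """
    if expr.n_samples < 6:
        raise ValueError("need >= 6 samples for the age test")
    x = np.log2(expr.ages + 1)
    if x.std() <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("ages are constant")
    x = (x - x.mean()) / x.std()
    Y = log_expr(expr.values)
    n = expr.n_samples

    rss = _fit_rss(Y, x, max_degree)
    degree, f_p = _select_and_test(rss, n, max_degree)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[0], dtype=int)
    perm_pos = np.zeros(n_perm)
    for k in range(n_perm):
        xp = x[rng.permutation(n)]
        rss_p = _fit_rss(Y, xp, max_degree)
        _, f_p_perm = _select_and_test(rss_p, n, max_degree)
        exceed += f_p_perm <= f_p
        perm_pos[k] = int((f_p_perm < p_cut).sum())
    perm_p = (1 + exceed) / (n_perm + 1)

    observed_pos = int((perm_p < p_cut).sum())
    fdr = float(perm_pos.mean() / observed_pos) if observed_pos else 1.0

    return [
        AgeTestResult(tid, int(d), float(fp), float(pp), fdr)
        for tid, d, fp, pp in zip(expr.ids, degree, f_p, perm_p)
    ]


def cluster_trajectories(
    results: list[AgeTestResult],
    expr: ExpressionMatrix,
    novel_ids: set[str],
    k: int = 12,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[dict[str, int], list]:
    """K-means on standardized significant trajectories + per-cluster Fisher
    enrichment of novel transcripts (Bonferroni across the k clusters)."""
    sig = [r for r in results if r.significant]
    if len(sig) < k:
        raise ValueError(f"only {len(sig)} significant transcripts for k={k}")
    ids = [r.transcript_id for r in sig]
    Y = log_expr(expr.subset(ids).values)
    sd = Y.std(axis=1, keepdims=True)
    Z = (Y - Y.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(Z)
    labels = {tid: int(lbl) + 1 for tid, lbl in zip(ids, km.labels_)}
    for r in sig:
        r.cluster = labels[r.transcript_id]

    n_novel = sum(1 for t in ids if t in novel_ids)
    n_ann = len(ids) - n_novel
    tests = []
    for c in range(1, k + 1):
        members = [t for t in ids if labels[t] == c]
        if not members:
            log.info("trajectory cluster %d is empty", c)
        a = sum(1 for t in members if t in novel_ids)
        b = len(members) - a
        res = fisher_enrichment(f"cluster{c}", a, b, n_novel - a, n_ann - b)
        res.q = min(1.0, res.p * k)  # Bonferroni
        tests.append(res)
    return labels, tests


def tissue_class(
    panel: pd.DataFrame,
    min_mean: float = 0.1,
    specific_share: float = 0.75,
    ubiquitous_breadth: float = 0.8,
) -> pd.Series:
    """Classify transcripts as tissue_specific / tissue_selective / ubiquitous.

    ``panel`` is transcripts x tissues RPKM. A transcript is expressed in a
    tissue when its value exceeds ``min_mean``. Specific: one expressing
    tissue, or top-tissue share of total >= ``specific_share``; ubiquitous:
    expressed in >= ``ubiquitous_breadth`` of tissues with top share <= 4/T;
    selective otherwise. Transcripts with mean <= ``min_mean`` are dropped.
    """
    T = panel.shape[1]
    if T < 3:
        raise ValueError("need >= 3 tissues")
    vals = panel.to_numpy(dtype=float)
    keep = vals.mean(axis=1) > min_mean
    vals = vals[keep]
    expressed = vals > min_mean
    n_expr = expressed.sum(axis=1)
    total = vals.sum(axis=1)
    top_share = vals.max(axis=1) / np.where(total == 0, 1, total)

    out = np.full(len(vals), "tissue_selective", dtype=object)
    out[(n_expr == 1) | (top_share >= specific_share)] = "tissue_specific"
    ubi = (n_expr >= ubiquitous_breadth * T) & (top_share <= 2 * (2 / T)) \
        & (out == "tissue_selective")
    out[ubi] = "ubiquitous"
    return pd.Series(out, index=panel.index[keep], name="tissue_class")


def localization_ratio(cytosol_rpkm, nucleus_rpkm, pseudo: float = 0.01) -> np.ndarray:
    """log2((cytosol + pseudo) / (nucleus + pseudo)) per transcript."""
    c = np.asarray(cytosol_rpkm, dtype=float)
    n = np.asarray(nucleus_rpkm, dtype=float)
    return np.log2((c + pseudo) / (n + pseudo))


def strandedness_qc(sense_counts: pd.DataFrame, antisense_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample strand-specificity summary from gene x sample count tables.

    Returns sense fraction (total sense / total) and the Pearson correlation
    of per-gene log counts between strands; all-zero samples are flagged.
    """
    if not sense_counts.columns.equals(antisense_counts.columns):
        raise ValueError("sense and antisense tables must share samples")
    rows = []
    for s in sense_counts.columns:
        a = sense_counts[s].to_numpy(dtype=float)
        b = antisense_counts[s].to_numpy(dtype=float)
        tot = a.sum() + b.sum()
        flagged = tot == 0
        frac = float("nan") if flagged else a.sum() / tot
        la, lb = np.log2(a + 1), np.log2(b + 1)
        r = float("nan")
        if not flagged and la.std() > 0 and lb.std() > 0:
            r = float(np.corrcoef(la, lb)[0, 1])
        rows.append(dict(sample=s, sense_fraction=frac, cross_strand_r=r,
                         flagged=flagged))
    return pd.DataFrame(rows).set_index("sample")
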