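"""MATCH-style PWM scanning, dinucleotide shuffling and TFBS enrichment.

Scoring follows the information-weighted similarity of the MATCH scheme:
with per-column frequencies f(p, b) (pseudocount 0.01 per cell) and column
information I(p) = sum_b f(p,b) ln(4 f(p,b)), the raw score of a window is
sum_p I(p) f(p, b_p), normalized to

    mss = (score - min) / (max - min)

where min/max substitute the per-column minimal/maximal frequencies. The
core similarity css applies the same formula over the five consecutive
positions of highest information. A hit requires css >= core_cut and
mss >= matrix_cut (defaults 0.95 / 0.90).

Dinucleotide shuffling is the Euler-path (Altschul-Erickson) construction:
the output is a uniform random sequence with the exact dinucleotide multiset
of the input and identical first and last nucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stats import bh_adjust, fisher_enrichment

log = logging.getLogger(__name__)

DEFAULT_CORE_CUT = 0.95
DEFAULT_MATRIX_CUT = 0.90
CORE_LEN = 5

_CODE = {b: i for i, b in enumerate("ACGT")}
_COMP_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass
class PWM:
    matrix_id: str
    counts: np.ndarray  # (L, 4) A C G T
    core_cut: float = DEFAULT_CORE_CUT
    matrix_cut: float = DEFAULT_MATRIX_CUT
    name: str = ""

    freqs: np.ndarray = field(init=False)
    info: np.ndarray = field(init=False)
    core_positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.matrix_id}: counts must be L x 4")
        if counts.shape[0] < 1:
            raise ValueError(f"{self.matrix_id}: matrix must have >= 1 position")
        if np.any(counts < 0) or np.any(counts.sum(axis=1) <= 0):
            raise ValueError(f"{self.matrix_id}: column sums must be positive")
        self.counts = counts
        # normalize to frequencies first so column scaling is exactly neutral,
        # then regularize with a 0.01-per-cell pseudocount
        f0 = counts / counts.sum(axis=1, keepdims=True)
        f = (f0 + 0.01) / 1.04
        self.freqs = f
        self.info = (f * np.log(4 * f)).sum(axis=1)
        if np.allclose(self.info, 0):
            raise ValueError(f"{self.matrix_id}: degenerate matrix (zero information)")
        L = len(self.info)
        k = min(CORE_LEN, L)
        sums = np.convolve(self.info, np.ones(k), mode="valid")
        start = int(np.argmax(sums))
        self.core_positions = np.arange(start, start + k)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.freqs.argmax(axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.freqs.argmin(axis=1))

    def _norm_parts(self, positions) -> tuple[np.ndarray, float, float]:
        w = self.info[positions, None] * self.freqs[positions]
        return w, float(w.min(axis=1).sum()), float(w.max(axis=1).sum())


@dataclass
class TfbsHit:
    matrix_id: str
    promoter_id: str
    position: int
    strand: str
    mss: float
    css: float


def read_transfac(path) -> list[PWM]:
    """Parse a TRANSFAC-format matrix library (ID / P0 / numbered rows / //)."""
    pwms = []
    mid, name, rows = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("ID"):
                mid = line.split(None, 1)[1].strip()
                rows, name = [], ""
            elif line.startswith(("BF", "NA")):
                name = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else ""
            elif line[:2].isdigit():
                parts = line.split()
                rows.append([float(x) for x in parts[1:5]])
            elif line.startswith("//") and mid is not None:
                pwms.append(PWM(matrix_id=mid, counts=np.array(rows), name=name))
                mid, rows = None, []
    return pwms


def read_profiles(path) -> dict[str, tuple[float, float]]:
    """Per-matrix cutoff profile: lines of `matrix_id core_cut matrix_cut`."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _scan_strand(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """(mss, css) for every window start on one strand; NaN where N present."""
    L = len(pwm)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    ok = (win != 4).all(axis=1)
    safe = np.where(win == 4, 0, win)
    w_all, mn_all, mx_all = pwm._norm_parts(np.arange(L))
    contrib = w_all[np.arange(L)[None, :], safe]
    score = contrib.sum(axis=1)
    mss = (score - mn_all) / (mx_all - mn_all)
    core = pwm.core_positions
    w_c, mn_c, mx_c = pwm._norm_parts(core)
    score_c = contrib[:, core].sum(axis=1)
    css = (score_c - mn_c) / (mx_c - mn_c)
    mss[~ok] = np.nan
    css[~ok] = np.nan
    return mss, css


def scan(sequence: str, pwm: PWM, promoter_id: str = "") -> list[TfbsHit]:
    """Scan both strands; positions are forward-strand offsets of hit starts."""
    codes = encode(sequence)
    L = len(pwm)
    hits = []
    for strand, c in (("+", codes), ("-", _COMP_CODE[codes][::-1])):
        mss, css = _scan_strand(c, pwm)
        sel = np.flatnonzero((mss >= pwm.matrix_cut) & (css >= pwm.core_cut))
        for i in sel:
            pos = int(i) if strand == "+" else len(codes) - int(i) - L
            hits.append(TfbsHit(pwm.matrix_id, promoter_id, pos, strand,
                                float(mss[i]), float(css[i])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# dinucleotide shuffle


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator = 0) -> str:
    """Altschul-Erickson shuffle preserving the dinucleotide multiset.

    The first and last nucleotides are fixed; the remaining edges of the
    dinucleotide multigraph are ordered uniformly at random subject to the
    Eulerian-path constraint (random last-edge tree plus edge shuffling).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(sequence)
    if n < 2:
        return sequence
    seq = sequence.upper()
    verts = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    non_empty = [v for v in verts if edges[v] and v != last]
    while True:
        last_edge = {}
        for v in non_empty:
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # connectivity: following chosen last edges from each vertex reaches `last`
        ok = True
        for v in non_empty:
            cur, steps = v, 0
            while cur != last and cur in last_edge and steps <= len(verts):
                cur = last_edge[cur]
                steps += 1
            if cur != last:
                ok = False
                break
        if ok:
            break

    arranged: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        arranged[v] = rest

    out = [seq[0]]
    ptr = {v: 0 for v in verts}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = arranged[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# enrichment and profiles


def enrich(
    nbip_hits: list[TfbsHit],
    kbip_hits: list[TfbsHit],
    n_nbip: int,
    n_kbip: int,
    q_cut: float = 0.05,
    or_cut: float = 1.3,
):
    """Per-matrix 2x2 enrichment of hit-bearing promoters, NBiP vs KBiP.

    Returns EnrichmentResults (one per matrix appearing in either set) with
    BH-adjusted q; a matrix is NBiP-enriched iff q < ``q_cut`` and odds ratio
    > ``or_cut``, and symmetrically KBiP-enriched iff q < q_cut and OR <
    1/or_cut.
    """
    def promoters_with(hits):
        d: dict[str, set[str]] = {}
        for h in hits:
            d.setdefault(h.matrix_id, set()).add(h.promoter_id)
        return d

    nd, kd = promoters_with(nbip_hits), promoters_with(kbip_hits)
    results = []
    for mid in sorted(set(nd) | set(kd)):
        a = len(nd.get(mid, ()))
        c = len(kd.get(mid, ()))
        results.append(fisher_enrichment(mid, a, n_nbip - a, c, n_kbip - c))
    qs = bh_adjust([r.p for r in results])
    enriched_nbip, enriched_kbip = [], []
    for r, q in zip(results, qs):
        r.q = float(q)
        if r.q < q_cut and r.odds_ratio > or_cut:
            enriched_nbip.append(r)
        if r.q < q_cut and r.odds_ratio < 1 / or_cut:
            enriched_kbip.append(r)
    return results, enriched_nbip, enriched_kbip


def density_profile(
    promoter_seqs: list[str],
    pwm: PWM,
    n_shuffles: int = 1000,
    seed: int = 0,
    central_fraction: float = 0.2,
) -> dict:
    """Per-position hit-start density with a dinucleotide-shuffle null band.

    All windows must share one length. The null band holds the per-position
    2.5th/97.5th percentiles of densities over shuffled sequence sets; the
    central-peak flag is set when the observed combined-strand density
    exceeds the upper band anywhere in the central fifth of the window.
    """
    lens = {len(s) for s in promoter_seqs}
    if len(lens) != 1:
        raise ValueError("promoter windows must share one length")
    W = lens.pop()
    rng = np.random.default_rng(seed)

    def profile(seqs):
        prof = np.zeros(W)
        for k, s in enumerate(seqs):
            for h in scan(s, pwm, promoter_id=str(k)):
                prof[h.position] += 1
        return prof / len(seqs)

    observed = profile(promoter_seqs)
    band = None
    central_peak = False
    if n_shuffles > 0:
        null = np.empty((n_shuffles, W))
        for k in range(n_shuffles):
            null[k] = profile([dinucleotide_shuffle(s, rng) for s in promoter_seqs])
        band = np.percentile(null, [2.5, 97.5], axis=0)
        lo = int(W * (0.5 - central_fraction / 2))
        hi = int(W * (0.5 + central_fraction / 2))
        central_peak = bool((observed[lo:hi] > band[1, lo:hi]).any())
    return {"observed": observed, "band": band, "central_peak": central_peak}


def tf_target_correlation(
    tf_expression: np.ndarray,
    target_sets: dict[str, list[str]],
    expression,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Mean TF-target Pearson r against random same-size target draws.

    ``tf_expression`` maps TF name -> vector when a dict, else a single
    vector used for every set; ``expression`` supplies target vectors via
    ``vector(id)`` and the permutation universe via ``ids``.
    """
    from .stats import log_expr

    if expression.n_samples < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    universe = [t for t in expression.ids
                if np.std(log_expr(expression.vector(t))) > 0]
    uni_mat = np.vstack([log_expr(expression.vector(t)) for t in universe])
    uni_idx = {t: i for i, t in enumerate(universe)}

    out = {}
    for tf, targets in sorted(target_sets.items()):
        v = tf_expression[tf] if isinstance(tf_expression, dict) else tf_expression
        lv = log_expr(np.asarray(v, dtype=float))
        if lv.std() == 0:
            raise ValueError(f"zero-variance TF expression vector for {tf}")
        rows = [uni_idx[t] for t in targets if t in uni_idx]
        if not rows:
            continue

        def mean_r(indices):
            M = uni_mat[indices]
            lc = lv - lv.mean()
            Mc = M - M.mean(axis=1, keepdims=True)
            num = Mc @ lc
            den = np.sqrt((Mc**2).sum(axis=1) * (lc**2).sum())
            return float((num / den).mean())

        obs = mean_r(rows)
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = mean_r(rng.choice(len(universe), size=len(rows), replace=False))
        p = (1 + int((null >= obs).sum())) / (n_perm + 1)
        out[tf] = {"mean_r": obs, "p": p, "n_targets": len(rows), "null": null}
    return out
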