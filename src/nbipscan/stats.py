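"""Shared statistical helpers: 2x2 enrichment records, BH, empirical p."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    """2x2 contingency with Fisher's exact test and BH-adjusted q."""

    label: str
    a: int  # feature present, group 1
    b: int  # feature absent, group 1
    c: int  # feature present, group 2
    d: int  # feature absent, group 2
    odds_ratio: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")

    def compute(self) -> "EnrichmentResult":
        table = [[self.a, self.b], [self.c, self.d]]
        self.p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            self.odds_ratio = float("inf") if num > 0 else float("nan")
        else:
            self.odds_ratio = num / den
        return self


def fisher_enrichment(label: str, a: int, b: int, c: int, d: int) -> EnrichmentResult:
    return EnrichmentResult(label, a, b, c, d).compute()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def empirical_p(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """(1 + #null as-or-more-extreme) / (n + 1)."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (len(null) + 1)


def log_expr(x, pseudo: float = 0.1) -> np.ndarray:
    """log2(RPKM + pseudo), the variance-stabilizing transform used throughout."""
    return np.log2(np.asarray(x, dtype=float) + pseudo)


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between matched rows of two matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den
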