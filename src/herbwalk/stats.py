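"""Overlap significance, enrichment arithmetic, FDR correction, DEG filtering.

The central quantity is the hypergeometric upper tail: given a background of
``N`` proteins of which ``K`` are disease-associated, and an entity targeting
``n`` proteins of which ``k`` hit the disease set, ``P(X >= k)`` under random
sampling without replacement measures how surprising the overlap is.  Two
enrichment summaries of the same test are emitted because both conventions
appear in practice: fold-enrichment ``(k/n)/(K/N)`` and ``-log10(p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapTest:
    """Hypergeometric overlap test result for one entity vs the disease set."""

    N: int
    K: int
    n: int
    k: int
    p_value: float
    fold_enrichment: float
    neglog10_p: float

    @classmethod
    def run(cls, k: int, n: int, K: int, N: int) -> "OverlapTest":
        p = hypergeom_tail(k, n, K, N)
        return cls(
            N=N, K=K, n=n, k=k,
            p_value=p,
            fold_enrichment=fold_enrichment(k, n, K, N),
            neglog10_p=neglog10(p),
        )


@dataclass
class DegRecord:
    """One gene's differential-expression statistics."""

    gene_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adj_p <= 1.0:
            raise ValueError("adjusted p must lie in [0, 1]")


def _check_hypergeom_params(k: int, n: int, K: int, N: int) -> None:
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    if K > N or n > N:
        raise ValueError("K and n cannot exceed the background size N")
    if k > min(n, K):
        raise ValueError("overlap k cannot exceed min(n, K)")


def _log_pmf(i: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    # log C(K, i) + log C(N-K, n-i) - log C(N, n)
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for X ~ Hypergeom(N, K, n).

    Summed in log space so that extreme overlaps (p far below float
    underflow of a naive product) remain accurate.
    """
    _check_hypergeom_params(k, n, K, N)
    hi = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, hi + 1)
    if support.size == 0:
        return 0.0
    return float(np.exp(logsumexp(_log_pmf(support, n, K, N))))


def fold_enrichment(
    k: float, n: float, K: float, N: float
) -> float:
    """Overlap density relative to the background density: ``(k/n) / (K/N)``."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("fold enrichment requires positive n, K, N")
    return (k / n) / (K / N)


def neglog10(p: float) -> float:
    """``-log10(p)`` for ``0 < p <= 1``."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return float(-np.log10(p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def filter_degs(
    records: Iterable[DegRecord], fc_min: float = 1.0, q_max: float = 0.05
) -> set[str]:
    """Significant DEGs: ``|log2fc| >= fc_min`` and ``adj_p < q_max`` (strict)."""
    return {
        rec.gene_id
        for rec in records
        if abs(rec.log2fc) >= fc_min and rec.adj_p < q_max
    }
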