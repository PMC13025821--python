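"""Over-representation analysis of target sets against gene-set libraries.

For each library term the 2x2 table (query vs term membership over a fixed
background) yields a hypergeometric upper-tail p-value, an odds ratio
(Haldane 0.5 continuity correction when any cell is zero), and a z-score of
the observed overlap under the hypergeometric null.  The combined score
``-ln(p) * z`` merges significance and effect size into one ranking
statistic.  This z-score is an offline approximation: rank-based z-scores
computed server-side against precomputed expected ranks (as popular web
services do) are not reproducible without their internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .stats import bh_adjust, hypergeom_tail


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets with an optional explicit background."""

    name: str
    terms: dict[str, set[str]]
    background: set[str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
        if self.background is not None:
            union = set().union(*self.terms.values())
            if not union <= self.background:
                raise ValueError("background must contain every term gene")


@dataclass
class EnrichmentRow:
    """One term's over-representation statistics."""

    term: str
    k: int  # overlap
    m: int  # term size
    p: float
    q: float = float("nan")
    odds_ratio: float = float("nan")
    z_score: float = float("nan")
    combined_score: float = float("nan")
    significant: bool = False
    overlap_genes: list[str] = field(default_factory=list)


class GMTParseError(ValueError):
    pass


def load_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file (term, description, genes...; tab-separated)."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            genes = {g for g in fields[2:] if g}
            if len(fields) < 3 or not fields[0] or not genes:
                raise GMTParseError(
                    f"{path}:{lineno}: expected term, description and >=1 gene"
                )
            terms[fields[0]] = genes
    return GeneSetLibrary(name=path.stem, terms=terms)


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    # a: in query & term, b: in query only, c: in term only, d: in neither
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _hypergeom_z(k: int, n: int, m: int, N: int) -> float:
    """Standardized overlap under Hypergeom(N, m, n)."""
    mean = n * m / N
    var = n * m * (N - m) * (N - n) / (N * N * (N - 1)) if N > 1 else 0.0
    if var == 0.0:
        return 0.0
    return (k - mean) / math.sqrt(var)


def ora(
    query: set[str],
    library: GeneSetLibrary,
    background_size: int | None = None,
    q_threshold: float = 0.05,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` in every library term.

    ``background_size`` defaults to the library's explicit background, which
    also restricts the query.  Rows are returned sorted by p ascending with
    lexicographic term ties; significance flags use BH q < ``q_threshold``.
    """
    if not query:
        raise ValueError("query gene set is empty")
    if background_size is None:
        if library.background is None:
            raise ValueError("no background: pass background_size or set library.background")
        background_size = len(library.background)
        query = query & library.background
        if not query:
            raise ValueError("query is disjoint from the library background")
    if background_size < len(query):
        raise ValueError("background smaller than the query set")

    rows: list[EnrichmentRow] = []
    for term in sorted(library.terms):
        genes = library.terms[term]
        m = len(genes)
        if m > background_size:
            raise ValueError(f"term {term!r} larger than the background")
        overlap = sorted(query & genes)
        k = len(overlap)
        n = len(query)
        p = hypergeom_tail(k, n, m, background_size)
        a = k
        b = n - k
        c = m - k
        d = background_size - n - m + k
        z = _hypergeom_z(k, n, m, background_size)
        combined = 0.0 if p >= 1.0 else -math.log(p) * z
        rows.append(
            EnrichmentRow(
                term=term, k=k, m=m, p=p,
                odds_ratio=_odds_ratio(a, b, c, d),
                z_score=z,
                combined_score=combined,
                overlap_genes=overlap,
            )
        )
    q_values = bh_adjust([row.p for row in rows])
    for row, q in zip(rows, q_values):
        row.q = q
        row.significant = q < q_threshold
    rows.sort(key=lambda row: (row.p, row.term))
    return rows


def write_enrichment(rows: list[EnrichmentRow], path: str | Path) -> None:
    """TSV export: Term, Overlap, p, q, Odds Ratio, Combined Score, Target Proteins."""
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "term\toverlap\tp\tq\todds_ratio\tz_score\tcombined_score\tgenes\n"
        )
        for row in rows:
            handle.write(
                f"{row.term}\t{row.k}/{row.m}\t{row.p:.6g}\t{row.q:.6g}\t"
                f"{row.odds_ratio:.4g}\t{row.z_score:.4g}\t"
                f"{row.combined_score:.4g}\t{','.join(row.overlap_genes)}\n"
            )
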