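"""Hypergeometric over-representation of SNP sets and gene lists, with BH-FDR.

The null model draws ``r`` elements (e.g. a context's eQTL SNPs) without
replacement from a background of ``m`` query elements (e.g. GWAS risk SNPs)
plus ``n`` non-query elements; the upper-tail probability of observing at
least ``k`` overlaps is

    P(X >= k) = 1 - sum_{i=0}^{k-1} C(m, i) C(n, r-i) / C(m+n, r).

The enrichment factor is the observed/expected overlap ``k / (r m / (m+n))``.
p-values are adjusted per analysis family with Benjamini–Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_contexts",
    "ora_gmt",
    "read_gmt",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts of one hypergeometric test.

    m: query elements (GWAS SNPs / query genes); n: non-query background
    elements; r: drawn set size (context eQTL SNPs / gene-set size);
    k: observed overlap.
    """

    m: int
    n: int
    r: int
    k: int

    def __post_init__(self) -> None:
        if min(self.m, self.n, self.r, self.k) < 0:
            raise ValueError("all counts must be non-negative")
        if self.k > min(self.m, self.r):
            raise ValueError("overlap k cannot exceed min(m, r)")
        if self.r > self.m + self.n:
            raise ValueError("draw size r cannot exceed background m+n")

    @property
    def expected(self) -> float:
        return self.r * self.m / (self.m + self.n) if self.m + self.n else 0.0

    @property
    def enrichment_factor(self) -> float:
        exp = self.expected
        return self.k / exp if exp > 0 else float("nan")


@dataclass(frozen=True)
class EnrichmentResult:
    context: str
    input: EnrichmentInput
    p: float
    p_adj: Optional[float] = None

    @property
    def enrichment_factor(self) -> float:
        return self.input.enrichment_factor


def hypergeom_upper_tail(inp: EnrichmentInput) -> float:
    """Exact P(X >= k); stable to m+n ~ 1e7 via scipy's log-space survival."""
    if inp.k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); population m+n, m successes, r draws
    return float(stats.hypergeom.sf(inp.k - 1, inp.m + inp.n, inp.m, inp.r))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _attach_adjusted(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    adj = bh_adjust([r.p for r in results])
    return [EnrichmentResult(r.context, r.input, r.p, float(a))
            for r, a in zip(results, adj)]


def enrich_contexts(
    query_snps: Set[str],
    contexts: Mapping[str, Set[str]],
    genome_background: int,
) -> list[EnrichmentResult]:
    """Overlap enrichment of a query SNP set in each context's eQTL SNP set.

    ``genome_background`` is the total number of SNPs in the genome-wide
    universe; it must be at least as large as any set involved. BH adjustment
    is applied across the supplied contexts (one family per call — pass brain
    regions and cell types separately to adjust within family).
    """
    m = len(query_snps)
    results = []
    for label, snps in contexts.items():
        r = len(snps)
        if genome_background < max(m + r - len(query_snps & snps), m, r):
            raise ValueError("genome background smaller than the sets it must contain")
        k = len(query_snps & snps)
        inp = EnrichmentInput(m=m, n=genome_background - m, r=r, k=k)
        results.append(EnrichmentResult(label, inp, hypergeom_upper_tail(inp)))
    return _attach_adjusted(results)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into {set name: member genes}."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def ora_gmt(
    gene_list: Iterable[str],
    gmt_sets: Mapping[str, Iterable[str]],
    universe_size: int,
) -> list[EnrichmentResult]:
    """Over-representation of a gene list in each GMT set (same statistic as
    :func:`enrich_contexts`, with genes as elements; symbols upper-cased)."""
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    query = {g.upper() for g in gene_list}
    m = len(query)
    results = []
    for name, members in gmt_sets.items():
        members = {g.upper() for g in members}
        r = len(members)
        if universe_size < max(m, r):
            raise ValueError("universe smaller than the sets it must contain")
        k = len(query & members)
        inp = EnrichmentInput(m=m, n=universe_size - m, r=r, k=k)
        results.append(EnrichmentResult(name, inp, hypergeom_upper_tail(inp)))
    return _attach_adjusted(results)


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tidy table (context, k, r, p, p_adj, enrichment_factor) sorted by k desc."""
    rows = [
        (r.context, r.input.k, r.input.r, r.p, r.p_adj, r.enrichment_factor)
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["context", "k", "r", "p", "p_adj",
                                     "enrichment_factor"])
    return df.sort_values(["k", "context"], ascending=[False, True]).reset_index(
        drop=True)
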