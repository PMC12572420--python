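"""Gene-window annotation of novel loci and PoPS-based gene prioritisation.

For each novel SNP we collect every gene whose body intersects a +/- 500 kb
window around the SNP, report the nearest gene with its distance (0 when the
SNP falls inside the gene body), and attach the window gene with the highest
polygenic priority score (PoPS). Negative PoPS scores are legitimate maxima;
score ties break by proximity to the SNP, then lexicographically by symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "AnnotatedLocus",
    "read_gene_bed",
    "read_pops_scores",
    "genes_in_window",
    "match_pops",
    "annotate_loci",
    "write_annotation_table",
    "read_annotation_table",
]

TABLE_COLUMNS = [
    "SNP", "CHR", "BP", "EA", "OA", "beta", "se", "P",
    "Nearest_Gene", "Distance", "ALL_genes", "PoPS_gene", "PoPS_score",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene body on 1-based inclusive coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def distance_to(self, pos: int) -> int:
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass(frozen=True)
class AnnotatedLocus:
    snp_id: str
    chrom: str
    pos: int
    ea: str
    oa: str
    beta: float
    se: float
    p: float
    nearest_gene: Optional[str]
    distance: Optional[int]
    all_genes: tuple[str, ...]
    pops_gene: Optional[str]
    pops_score: Optional[float]


def read_gene_bed(path) -> list[GeneRecord]:
    """Read gene annotation from BED-like text (chrom, start, end, gene_id, symbol).

    BED coordinates are 0-based half-open; they are converted to 1-based
    inclusive on read.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "symbol"],
                     dtype={"chrom": str})
    return [
        GeneRecord(str(t.gene_id), str(t.symbol), str(t.chrom),
                   int(t.start) + 1, int(t.end))
        for t in df.itertuples(index=False)
    ]


def read_pops_scores(path) -> dict[str, float]:
    """Two-column delimited text (symbol, score) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    sym, score = df.columns[:2]
    return dict(zip(df[sym].astype(str), df[score].astype(float)))


def genes_in_window(
    snp_chrom: str,
    snp_pos: int,
    genes: Sequence[GeneRecord],
    window_kb: float = 500.0,
) -> tuple[list[GeneRecord], Optional[GeneRecord], Optional[int]]:
    """Genes intersecting [pos - window, pos + window] on the SNP's chromosome.

    Returns ``(window_genes, nearest_gene, distance)``; nearest is the gene
    with minimal body distance (ties by symbol for determinism). Empty window
    yields ``([], None, None)``.
    """
    window = window_kb * 1000.0
    lo, hi = snp_pos - window, snp_pos + window
    hits = [g for g in genes
            if g.chrom == snp_chrom and g.start <= hi and g.end >= lo]
    if not hits:
        return [], None, None
    nearest = min(hits, key=lambda g: (g.distance_to(snp_pos), g.symbol))
    return hits, nearest, nearest.distance_to(snp_pos)


def match_pops(
    window_genes: Sequence[GeneRecord],
    pops_table: Mapping[str, float],
    snp_pos: Optional[int] = None,
) -> tuple[Optional[str], Optional[float]]:
    """Highest-PoPS gene among the window genes present in the score table.

    Returns ``(None, None)`` when no window gene is scored. Ties on the
    maximal score break by distance to the SNP (when its position is given),
    then lexicographically by symbol.
    """
    scored = [g for g in window_genes if g.symbol in pops_table]
    if not scored:
        return None, None

    def sort_key(g: GeneRecord):
        dist = g.distance_to(snp_pos) if snp_pos is not None else 0
        return (-pops_table[g.symbol], dist, g.symbol)

    best = min(scored, key=sort_key)
    return best.symbol, float(pops_table[best.symbol])


def annotate_loci(
    novel: pd.DataFrame,
    genes: Sequence[GeneRecord],
    pops_table: Mapping[str, float],
    window_kb: float = 500.0,
) -> list[AnnotatedLocus]:
    """Annotate each novel SNP row (snp, chrom, pos, ea, oa, beta, se, p)."""
    out = []
    for t in novel.itertuples(index=False):
        hits, nearest, dist = genes_in_window(str(t.chrom), int(t.pos), genes,
                                              window_kb)
        pg, ps = match_pops(hits, pops_table, snp_pos=int(t.pos))
        out.append(AnnotatedLocus(
            snp_id=str(t.snp), chrom=str(t.chrom), pos=int(t.pos),
            ea=str(t.ea), oa=str(t.oa), beta=float(t.beta), se=float(t.se),
            p=float(t.p),
            nearest_gene=None if nearest is None else nearest.symbol,
            distance=dist,
            all_genes=tuple(sorted(g.symbol for g in hits)),
            pops_gene=pg, pops_score=ps,
        ))
    return out


def write_annotation_table(annotated: Iterable[AnnotatedLocus], path) -> None:
    """Serialize annotated loci with the 13-column annotation schema."""
    rows = [
        (a.snp_id, a.chrom, a.pos, a.ea, a.oa, a.beta, a.se, a.p,
         a.nearest_gene or "", "" if a.distance is None else a.distance,
         ";".join(a.all_genes),
         a.pops_gene or "", "" if a.pops_score is None else a.pops_score)
        for a in annotated
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> list[AnnotatedLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, keep_default_na=False,
                     na_values=[])
    out = []
    for t in df.itertuples(index=False):
        row = t._asdict()
        genes = tuple(g for g in str(row["ALL_genes"]).split(";") if g)
        ps = row["PoPS_score"]
        dist = row["Distance"]
        out.append(AnnotatedLocus(
            snp_id=str(row["SNP"]), chrom=str(row["CHR"]), pos=int(row["BP"]),
            ea=str(row["EA"]), oa=str(row["OA"]), beta=float(row["beta"]),
            se=float(row["se"]), p=float(row["P"]),
            nearest_gene=str(row["Nearest_Gene"]) or None,
            distance=None if dist == "" else int(float(dist)),
            all_genes=genes,
            pops_gene=str(row["PoPS_gene"]) or None,
            pops_score=None if ps == "" else float(ps),
        ))
    return out
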