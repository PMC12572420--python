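"""Cross-dimension intersection and joint reporting of hub SNPs.

The pipeline's final step asks which SNPs recur across analysis dimensions:
novel loci, MR instrument sets (per direction), SMR top SNPs across eQTL
panel versions, and enrichment contexts. SNPs satisfying many dimensions are
candidate pleiotropic hubs.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Set

import pandas as pd

__all__ = [
    "common_snps",
    "cross_version_top_overlap",
    "joint_report",
]

JOINT_COLUMNS = [
    "snp", "n_dimensions", "in_novel", "in_mr_forward", "in_mr_reverse",
    "smr_top_versions", "enriched_regions", "enriched_cells",
    "nearest_gene", "pops_gene",
]


def common_snps(
    instrument_sets: Mapping[str, Set[str]], novel: Set[str]
) -> dict[str, set[str]]:
    """Exact per-direction intersections between instrument SNPs and novel loci."""
    return {direction: set(snps) & set(novel)
            for direction, snps in instrument_sets.items()}


def cross_version_top_overlap(
    smr_tables: Mapping[str, pd.DataFrame], fdr_max: float = 0.05
) -> set[str]:
    """SNPs appearing as a significant top SNP in every eQTL panel version.

    Significance means FDR_BH < ``fdr_max`` within each version's scan.
    Requires at least two versions.
    """
    if len(smr_tables) < 2:
        raise ValueError("cross-version overlap needs at least two SMR tables")
    sets = []
    for _version, df in smr_tables.items():
        sig = df[df["FDR_BH"] < fdr_max] if len(df) else df
        sets.append(set(sig["topSNP"]) if len(sig) else set())
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def joint_report(
    novel: Set[str],
    mr_instruments: Optional[Mapping[str, Set[str]]] = None,
    smr_top_by_version: Optional[Mapping[str, Set[str]]] = None,
    enriched_regions_by_snp: Optional[Mapping[str, Sequence[str]]] = None,
    enriched_cells_by_snp: Optional[Mapping[str, Sequence[str]]] = None,
    nearest_gene: Optional[Mapping[str, str]] = None,
    pops_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """One row per SNP appearing in any dimension, ranked by dimension count.

    A dimension counts once per SNP: novel-locus membership, each MR
    direction's instrument set, each SMR version where the SNP is a top SNP,
    and presence in at least one enriched region / cell context. Ordering is
    deterministic: count descending, then snp id.
    """
    mr_instruments = mr_instruments or {}
    smr_top_by_version = smr_top_by_version or {}
    enriched_regions_by_snp = enriched_regions_by_snp or {}
    enriched_cells_by_snp = enriched_cells_by_snp or {}
    nearest_gene = nearest_gene or {}
    pops_gene = pops_gene or {}

    universe: set[str] = set(novel)
    for s in mr_instruments.values():
        universe |= set(s)
    for s in smr_top_by_version.values():
        universe |= set(s)
    universe |= set(enriched_regions_by_snp) | set(enriched_cells_by_snp)

    rows = []
    for snp in universe:
        in_novel = snp in novel
        fwd = snp in mr_instruments.get("forward", set())
        rev = snp in mr_instruments.get("reverse", set())
        versions = sorted(v for v, s in smr_top_by_version.items() if snp in s)
        regions = sorted(enriched_regions_by_snp.get(snp, []))
        cells = sorted(enriched_cells_by_snp.get(snp, []))
        count = (int(in_novel) + int(fwd) + int(rev) + len(versions)
                 + int(bool(regions)) + int(bool(cells)))
        rows.append((snp, count, in_novel, fwd, rev, ";".join(versions),
                     ";".join(regions), ";".join(cells),
                     nearest_gene.get(snp, ""), pops_gene.get(snp, "")))
    df = pd.DataFrame(rows, columns=JOINT_COLUMNS)
    return df.sort_values(["n_dimensions", "snp"],
                          ascending=[False, True]).reset_index(drop=True)
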