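"""Summary-data-based Mendelian randomization (SMR) against eQTL/mQTL panels.

For each expression probe, the top cis SNP (smallest eQTL p) instruments the
test of whether the GWAS association is mediated by expression. With
``z_gwas = b_gwas/se_gwas`` and ``z_eqtl = b_eqtl/se_eqtl``:

    b_SMR = b_gwas / b_eqtl
    T_SMR = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2)   ~ chi^2(1) under H0
    se_SMR = |b_SMR| sqrt(1/z_gwas^2 + 1/z_eqtl^2)      (first-order delta)

Probe-level p-values are BH-adjusted within a scan after de-duplication by
probe id. The HEIDI linkage test is deliberately absent: upstream LD pruning
is the pleiotropy guard in this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust
from .sumstats import SumStatRecord, align_to_reference

__all__ = [
    "EQTL_COLUMNS",
    "SMR_COLUMNS",
    "SmrValue",
    "select_top_snp",
    "smr_test",
    "smr_scan",
    "read_eqtl_table",
]

#: expected columns of a delimited eQTL association table
EQTL_COLUMNS = [
    "probe_id", "gene", "probe_chrom", "probe_bp", "snp", "snp_chrom",
    "snp_bp", "freq", "beta_eqtl", "se_eqtl", "p_eqtl",
]

#: output schema of an SMR scan
SMR_COLUMNS = [
    "probeID", "Gene", "ProbeChr", "Probe_bp", "topSNP", "topSNP_chr",
    "topSNP_bp", "Freq", "b_SMR", "se_SMR", "p_SMR", "FDR_BH",
]


class SmrValue(NamedTuple):
    b_smr: float
    se_smr: float
    p_smr: float


def read_eqtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_chrom": str, "snp_chrom": str})
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"eQTL table missing columns: {missing}")
    return df


def select_top_snp(
    cis_assocs: pd.DataFrame, p_eqtl_max: float = 5e-8
) -> Optional[pd.Series]:
    """Most significant cis association of one probe, or None if none passes.

    Ties on p break by larger |beta/se|, then by SNP position.
    """
    passing = cis_assocs[cis_assocs["p_eqtl"] <= p_eqtl_max]
    if passing.empty:
        return None
    absz = (passing["beta_eqtl"] / passing["se_eqtl"]).abs()
    order = passing.assign(_absz=absz).sort_values(
        ["p_eqtl", "_absz", "snp_bp"], ascending=[True, False, True],
        kind="mergesort")
    return order.iloc[0].drop("_absz")


def smr_test(b_gwas, se_gwas, b_eqtl, se_eqtl) -> SmrValue:
    """SMR effect, delta-method SE, and chi-square(1) p for one SNP-probe pair.

    Accepts scalars or arrays (broadcast; returns arrays in that case).
    """
    b_gwas = np.asarray(b_gwas, dtype=float)
    se_gwas = np.asarray(se_gwas, dtype=float)
    b_eqtl = np.asarray(b_eqtl, dtype=float)
    se_eqtl = np.asarray(se_eqtl, dtype=float)
    if np.any(b_eqtl == 0):
        raise ZeroDivisionError("b_eqtl = 0 gives an undefined SMR ratio")
    if np.any(se_gwas <= 0) or np.any(se_eqtl <= 0):
        raise ValueError("standard errors must be positive")
    z_g = b_gwas / se_gwas
    z_e = b_eqtl / se_eqtl
    b = b_gwas / b_eqtl
    t = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    p = stats.chi2.sf(t, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(b) * np.sqrt(1.0 / z_g**2 + 1.0 / z_e**2)
    # delta-method limit as b_gwas -> 0: |b| / |z_g| = se_gwas / |b_eqtl|
    se = np.where(z_g == 0, se_gwas / np.abs(b_eqtl), se)
    if b.ndim == 0:
        return SmrValue(float(b), float(se), float(p))
    return SmrValue(b, se, p)


def _align_gwas_to_eqtl(grow: pd.Series, erow: pd.Series) -> Optional[float]:
    """GWAS beta oriented to the eQTL effect allele (None -> unalignable)."""
    if "ea" not in grow or "oa" not in grow or "eqtl_ea" not in erow:
        return float(grow["beta"])
    rec = SumStatRecord(
        snp_id=str(grow["snp"]), chrom=str(grow.get("chrom", "")),
        pos=int(grow.get("pos", 0)), ea=str(grow["ea"]), oa=str(grow["oa"]),
        beta=float(grow["beta"]),
    )
    aligned, _status = align_to_reference(rec, str(erow["eqtl_ea"]),
                                          str(erow["eqtl_oa"]))
    return None if aligned is None else aligned.beta


def smr_scan(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    p_eqtl_max: float = 5e-8,
    snp_subset: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Run the SMR test for every probe whose top cis SNP appears in the GWAS.

    ``gwas`` is a pooled meta-analysis table (columns snp, beta, se, and
    optionally ea/oa for allele alignment when the eQTL table carries
    ``eqtl_ea``/``eqtl_oa``); ``eqtl`` follows :data:`EQTL_COLUMNS`. When
    ``snp_subset`` is given, only probes whose top SNP lies in it are tested.
    Probes are de-duplicated by probe id before the BH adjustment; output is
    sorted by probe position.
    """
    gw = gwas.drop_duplicates("snp").set_index("snp")
    rows = []
    for probe_id, sub in eqtl.groupby("probe_id", sort=False):
        top = select_top_snp(sub, p_eqtl_max)
        if top is None:
            continue
        snp = str(top["snp"])
        if snp_subset is not None and snp not in snp_subset:
            continue
        if snp not in gw.index:
            continue
        grow = gw.loc[snp]
        b_gwas = _align_gwas_to_eqtl(pd.Series({"snp": snp, **grow}), top)
        if b_gwas is None:
            continue
        val = smr_test(b_gwas, float(grow["se"]),
                       float(top["beta_eqtl"]), float(top["se_eqtl"]))
        rows.append((
            str(probe_id), str(top["gene"]), str(top["probe_chrom"]),
            int(top["probe_bp"]), snp, str(top["snp_chrom"]),
            int(top["snp_bp"]), float(top["freq"]),
            val.b_smr, val.se_smr, val.p_smr,
        ))
    if not rows:
        return pd.DataFrame(columns=SMR_COLUMNS)
    df = pd.DataFrame(rows, columns=SMR_COLUMNS[:-1])
    df = df.drop_duplicates("probeID")
    df["FDR_BH"] = bh_adjust(df["p_SMR"].to_numpy())
    return df.sort_values(["ProbeChr", "Probe_bp"]).reset_index(drop=True)
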