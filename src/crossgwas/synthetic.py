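"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the data layout of a cross-tissue
integration study: K case-control GWAS of one disorder sharing true per-SNP
effects (with controllable between-study heterogeneity tau^2), block-diagonal
LD with a tunable within-block r^2, cis-eQTL/mQTL panels in which a known
subset of probes is truly mediated (so the SMR ratio has a planted value), a
panel of exposure-trait GWAS (microbiota-abundance style, n ~ 6,000) with
planted forward and reverse causal effects on/of the disorder, and
enrichment contexts/gene sets with planted overlaps.

Summary statistics are simulated directly — no individual-level genotypes.
LD enters only through the pairwise r^2 table that clumping consumes, which
is exactly what the downstream pipeline reads. Everything is a pure function
of (config, seed): identical configs give byte-identical outputs.

Two designated *hub* SNPs carry a strong disorder effect, drive mediated
expression probes in every QTL panel version, sit inside every enrichment
context, and enter the reverse-MR instrument set — so a correct end-to-end
run must rank them first in the joint report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .loci import LdMatrix
from .sumstats import StudyMeta

__all__ = ["SimConfig", "SimData", "simulate_all", "sim_instruments"]

_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic world.

    Defaults mirror the motivating study design where it states them (four
    case-control GWAS with the listed sample sizes; an exposure panel with
    n = 5,959; 13 brain-region and 8 brain-cell eQTL contexts) and a
    desk-scale genome of 50,000 SNPs in 10-SNP LD blocks elsewhere.
    """

    seed: int = 0
    n_snps: int = 50_000
    ld_block_size: int = 10
    ld_block_r2: float = 0.8
    n_chromosomes: int = 22
    intra_block_spacing: int = 20_000  # bp between SNPs inside a block
    block_gap: int = 1_200_000  # bp between block starts (>> 500 kb window)
    maf_range: tuple[float, float] = (0.05, 0.5)

    # disorder GWAS panel
    case_control_sizes: tuple[tuple[int, int], ...] = (
        (18382, 27969), (18235, 36741), (888, 362304), (22916, 32504))
    prop_causal: float = 0.01
    effect_sd: float = 0.05
    tau2_between_study: float = 0.0
    n_eaf_outliers: int = 5  # SNPs planted with divergent cross-study eaf

    # hub SNPs
    n_hubs: int = 2
    hub_beta: float = 0.04

    # QTL panels
    n_genes: int = 200
    n_mediation_genes: int = 20
    mediation_beta: float = 0.5
    eqtl_effect_range: tuple[float, float] = (0.25, 0.8)
    eqtl_n: int = 2500
    decoys_per_probe: int = 2

    # exposure (microbiota) panel
    n_traits: int = 20
    n_causal_traits: int = 2
    causal_trait_beta: float = 0.15
    n_reverse_causal_traits: int = 2
    reverse_trait_beta: float = 0.15
    instruments_per_trait: int = 30
    exposure_effect_range: tuple[float, float] = (0.1, 0.2)
    microbiome_n: int = 5959

    # enrichment
    n_region_contexts: int = 13
    n_cell_contexts: int = 8
    context_size: int = 300
    genome_background: int = 1_000_000
    n_gene_sets: int = 15
    gene_set_size: int = 12

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.ld_block_size <= 0:
            raise ValueError("sizes must be positive")
        if not (0.0 <= self.ld_block_r2 <= 1.0):
            raise ValueError("ld_block_r2 must be in [0, 1]")
        if not (0.0 <= self.prop_causal <= 1.0):
            raise ValueError("prop_causal must be a proportion")

    @property
    def n_blocks(self) -> int:
        return self.n_snps // self.ld_block_size

    @property
    def studies(self) -> list[StudyMeta]:
        return [StudyMeta(f"study{i + 1}", c, k)
                for i, (c, k) in enumerate(self.case_control_sizes)]


@dataclass
class SimData:
    """Everything the pipeline consumes, plus per-stage truth tables."""

    config: SimConfig
    snp_map: pd.DataFrame  # snp, chrom, pos, ea, oa, eaf, block
    ld: LdMatrix
    studies: dict[str, pd.DataFrame]
    snp_truth: pd.DataFrame  # snp, true_beta, role, block
    qtl_versions: dict[str, pd.DataFrame]
    probe_truth: pd.DataFrame  # probe_id, top_snp, beta_eqtl, mediated, b_smr_true
    trait_sumstats: dict[str, pd.DataFrame]
    trait_truth: pd.DataFrame  # trait, forward_beta, reverse_beta
    region_contexts: dict[str, set[str]]
    cell_contexts: dict[str, set[str]]
    gene_bed: pd.DataFrame  # chrom, start0, end, gene_id, symbol
    pops_scores: dict[str, float]
    gene_sets: dict[str, list[str]]
    hub_snps: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        """Write every input as delimited text under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False)
        self.ld.to_table().to_csv(out / "ld.tsv", sep="\t", index=False)
        for sid, df in self.studies.items():
            df.to_csv(out / f"gwas_{sid}.tsv", sep="\t", index=False)
        self.snp_truth.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        for version, df in self.qtl_versions.items():
            df.to_csv(out / f"qtl_{version}.tsv", sep="\t", index=False)
        self.probe_truth.to_csv(out / "truth_probes.tsv", sep="\t", index=False)
        for trait, df in self.trait_sumstats.items():
            df.to_csv(out / f"trait_{trait}.tsv", sep="\t", index=False)
        self.trait_truth.to_csv(out / "truth_traits.tsv", sep="\t", index=False)
        for name, contexts in (("region", self.region_contexts),
                               ("cell", self.cell_contexts)):
            rows = [(label, snp) for label, snps in contexts.items()
                    for snp in sorted(snps)]
            pd.DataFrame(rows, columns=["context", "snp"]).to_csv(
                out / f"contexts_{name}.tsv", sep="\t", index=False)
        self.gene_bed.to_csv(out / "genes.bed", sep="\t", index=False,
                             header=False)
        pd.DataFrame(sorted(self.pops_scores.items()),
                     columns=["symbol", "score"]).to_csv(
            out / "pops.tsv", sep="\t", index=False)
        with open(out / "gene_sets.gmt", "w") as fh:
            for name, members in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
        pd.DataFrame({"hub": self.hub_snps}).to_csv(out / "truth_hubs.tsv",
                                                    sep="\t", index=False)


def _sim_ld_and_map(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_blocks * cfg.ld_block_size
    blocks = np.repeat(np.arange(cfg.n_blocks), cfg.ld_block_size)
    chrom_of_block = np.arange(cfg.n_blocks) % cfg.n_chromosomes
    block_rank = np.arange(cfg.n_blocks) // cfg.n_chromosomes
    within = np.tile(np.arange(cfg.ld_block_size), cfg.n_blocks)
    pos = (block_rank[blocks] * cfg.block_gap + 1_000_000
           + within * cfg.intra_block_spacing)
    eaf = rng.uniform(*cfg.maf_range, size=n)
    ea_idx = rng.integers(0, 4, size=n)
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4
    # avoid palindromic (complementary) pairs so no simulated SNP is lost to
    # strand-ambiguity filtering; palindromic handling is exercised by unit
    # tests on hand-built records
    palindromic = ea_idx + oa_idx == 3
    oa_idx[palindromic] = (ea_idx[palindromic] + 2) % 4
    snp_map = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "chrom": [f"chr{c + 1}" for c in chrom_of_block[blocks]],
        "pos": pos.astype(np.int64),
        "ea": _ALLELES[ea_idx],
        "oa": _ALLELES[oa_idx],
        "eaf": eaf,
        "block": blocks,
    })
    ld = LdMatrix()
    if cfg.ld_block_r2 > 0 and cfg.ld_block_size > 1:
        snps = snp_map["snp"].to_numpy()
        for b in range(cfg.n_blocks):
            ids = snps[b * cfg.ld_block_size:(b + 1) * cfg.ld_block_size]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    ld.set(ids[i], ids[j], cfg.ld_block_r2)
    return snp_map, ld


def _layout(cfg: SimConfig, rng: np.random.Generator):
    """Deterministic block-role assignment: hubs, probes, trait instruments."""
    order = rng.permutation(cfg.n_blocks)
    i = 0
    hubs = order[i:i + cfg.n_hubs]; i += cfg.n_hubs
    probes = order[i:i + cfg.n_genes]; i += cfg.n_genes
    need = cfg.n_traits * cfg.instruments_per_trait
    if i + need > cfg.n_blocks:
        raise ValueError("not enough LD blocks for the requested layout")
    inst = order[i:i + need].reshape(cfg.n_traits, cfg.instruments_per_trait)
    i += need
    free = order[i:]
    return hubs, probes, inst, free


def _mid_snp(cfg: SimConfig, block: int) -> int:
    return block * cfg.ld_block_size + cfg.ld_block_size // 2


def _se_from_eaf(eaf: np.ndarray, n_eff: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)


def sim_instruments(
    n: int,
    true_beta: float,
    seed: int = 0,
    se_exp: float = 0.02,
    se_out: float = 0.01,
    exposure_effect_range: tuple[float, float] = (0.1, 0.3),
    pleiotropy_sd: float = 0.0,
) -> pd.DataFrame:
    """Directly simulate a harmonized instrument table with a known causal slope.

    Useful for estimator parameter-recovery and type-I-error studies without
    running the full generator: beta_out = true_beta * beta_exp (+ optional
    balanced pleiotropy) plus sampling noise on both sides.
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*exposure_effect_range, size=n) * rng.choice([-1, 1], n)
    bx = bx_true + rng.normal(0.0, se_exp, n)
    pleio = rng.normal(0.0, pleiotropy_sd, n) if pleiotropy_sd > 0 else 0.0
    by = true_beta * bx_true + pleio + rng.normal(0.0, se_out, n)
    return pd.DataFrame({
        "snp": [f"iv{i + 1}" for i in range(n)],
        "beta_exp": bx, "se_exp": se_exp, "beta_out": by, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "f_stat": (bx / se_exp) ** 2,
    })


def simulate_all(cfg: SimConfig) -> SimData:
    """Generate every pipeline input with ground truth, from (config, seed)."""
    rng = np.random.default_rng(cfg.seed)
    snp_map, ld = _sim_ld_and_map(cfg, rng)
    n = len(snp_map)
    hubs, probe_blocks, inst_blocks, _free = _layout(cfg, rng)

    # --- true disorder effects -------------------------------------------
    true_beta = np.zeros(n)
    role = np.array(["null"] * n, dtype=object)
    causal = rng.random(n) < cfg.prop_causal
    true_beta[causal] = rng.normal(0.0, cfg.effect_sd, causal.sum())
    role[causal] = "polygenic"

    # reserved blocks carry only their planted signal
    reserved_blocks = set(hubs) | set(probe_blocks) | set(inst_blocks.flat)
    in_reserved = snp_map["block"].isin(reserved_blocks).to_numpy()
    true_beta[in_reserved] = 0.0
    role[in_reserved] = "null"

    reserved = set()
    hub_idx = [_mid_snp(cfg, b) for b in hubs]
    for i in hub_idx:
        true_beta[i] = cfg.hub_beta
        role[i] = "hub"
        reserved.add(i)
    hub_snps = [snp_map["snp"].iloc[i] for i in hub_idx]

    # --- QTL panel wiring -------------------------------------------------
    # Probe p uses top SNP at the middle of its block; the first
    # n_mediation_genes probes are truly mediated, with the hubs heading the
    # list so they are top SNPs of mediated probes in every panel version.
    probe_ids = [f"PROBE{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_symbols = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    top_idx = []
    for g, b in enumerate(probe_blocks):
        if g < cfg.n_hubs:
            top_idx.append(hub_idx[g])
        else:
            top_idx.append(_mid_snp(cfg, b))
    beta_eqtl = (rng.uniform(*cfg.eqtl_effect_range, size=cfg.n_genes)
                 * rng.choice([-1, 1], cfg.n_genes))
    mediated = np.zeros(cfg.n_genes, dtype=bool)
    mediated[:cfg.n_mediation_genes] = True
    b_smr_true = np.full(cfg.n_genes, np.nan)
    for g in range(cfg.n_genes):
        i = top_idx[g]
        if not mediated[g]:
            continue
        if g < cfg.n_hubs:  # hub effect is fixed; ratio follows from it
            b_smr_true[g] = cfg.hub_beta / beta_eqtl[g]
        else:
            true_beta[i] = cfg.mediation_beta * beta_eqtl[g]
            role[i] = "mediation"
            reserved.add(i)
            b_smr_true[g] = cfg.mediation_beta
    probe_truth = pd.DataFrame({
        "probe_id": probe_ids,
        "gene": gene_symbols,
        "top_snp": [snp_map["snp"].iloc[i] for i in top_idx],
        "beta_eqtl": beta_eqtl,
        "mediated": mediated,
        "b_smr_true": b_smr_true,
    })

    # --- exposure panel wiring -------------------------------------------
    trait_names = [f"taxon{t + 1:03d}" for t in range(cfg.n_traits)]
    exp_beta = np.zeros((cfg.n_traits, cfg.instruments_per_trait))
    inst_idx = np.empty_like(inst_blocks)
    for t in range(cfg.n_traits):
        for j, b in enumerate(inst_blocks[t]):
            inst_idx[t, j] = _mid_snp(cfg, b)
        exp_beta[t] = (rng.uniform(*cfg.exposure_effect_range,
                                   cfg.instruments_per_trait)
                       * rng.choice([-1, 1], cfg.instruments_per_trait))
    n_fwd = min(cfg.n_causal_traits, cfg.n_traits)
    n_rev = min(cfg.n_reverse_causal_traits, cfg.n_traits - n_fwd)
    fwd_causal = np.zeros(cfg.n_traits)
    fwd_causal[:n_fwd] = (
        cfg.causal_trait_beta * np.where(np.arange(n_fwd) % 2, -1, 1))
    rev_causal = np.zeros(cfg.n_traits)
    rev_causal[n_fwd:n_fwd + n_rev] = (
        cfg.reverse_trait_beta * np.where(np.arange(n_rev) % 2, -1, 1))
    for t in range(cfg.n_traits):
        for j in range(cfg.instruments_per_trait):
            i = inst_idx[t, j]
            true_beta[i] += fwd_causal[t] * exp_beta[t, j]
            if role[i] == "null":
                role[i] = "instrument"
            reserved.add(i)

    snp_truth = pd.DataFrame({
        "snp": snp_map["snp"], "true_beta": true_beta, "role": role,
        "block": snp_map["block"],
    })

    # --- disorder GWAS panel ---------------------------------------------
    eaf = snp_map["eaf"].to_numpy()
    studies: dict[str, pd.DataFrame] = {}
    tau = np.sqrt(cfg.tau2_between_study)
    eaf_outliers = rng.choice(np.where(role == "null")[0],
                              size=min(cfg.n_eaf_outliers, n), replace=False)
    for s, meta_s in enumerate(cfg.studies):
        n_eff = meta_s.n_effective
        se = _se_from_eaf(eaf, n_eff)
        study_true = true_beta + (rng.normal(0.0, tau, n) if tau > 0 else 0.0)
        beta_hat = study_true + rng.normal(0.0, 1.0, n) * se
        obs_eaf = np.clip(eaf + rng.uniform(-0.01, 0.01, n), 0.01, 0.99)
        if s == 0:
            shift = np.where(eaf[eaf_outliers] < 0.5, 0.35, -0.35)
            obs_eaf[eaf_outliers] = np.clip(eaf[eaf_outliers] + shift, 0.01, 0.99)
        z = beta_hat / se
        from .meta import two_sided_p
        studies[meta_s.study_id] = pd.DataFrame({
            "snp": snp_map["snp"], "chrom": snp_map["chrom"],
            "pos": snp_map["pos"], "ea": snp_map["ea"], "oa": snp_map["oa"],
            "eaf": obs_eaf, "beta": beta_hat, "se": se, "p": two_sided_p(z),
            "weight": n_eff, "z": z,
        })

    # --- QTL observed panels (two expression versions + one methylation) ---
    se_eqtl = _se_from_eaf(eaf[np.asarray(top_idx)], cfg.eqtl_n)
    qtl_versions: dict[str, pd.DataFrame] = {}
    from .meta import two_sided_p as _p2
    for version in ("eqtl_v1", "eqtl_v2", "mqtl"):
        rows = []
        noise = rng.normal(0.0, 1.0, (cfg.n_genes, 1 + cfg.decoys_per_probe))
        for g in range(cfg.n_genes):
            i = top_idx[g]
            prefix = "cg" if version == "mqtl" else ""
            pid = (f"{prefix}{probe_ids[g]}" if prefix else probe_ids[g])
            probe_bp = int(snp_map["pos"].iloc[i]) + 40_000
            snps = [i] + [i - 1 - d for d in range(cfg.decoys_per_probe)
                          if i - 1 - d >= 0
                          and snp_map["block"].iloc[i - 1 - d]
                          == snp_map["block"].iloc[i]]
            for rank, si in enumerate(snps):
                b_true = beta_eqtl[g] if rank == 0 else beta_eqtl[g] * 0.5
                se_q = float(se_eqtl[g]) * (1.0 if rank == 0 else 1.2)
                b_hat = b_true + noise[g, rank] * se_q
                rows.append((
                    pid, gene_symbols[g], str(snp_map["chrom"].iloc[i]),
                    probe_bp, str(snp_map["snp"].iloc[si]),
                    str(snp_map["chrom"].iloc[si]),
                    int(snp_map["pos"].iloc[si]), float(eaf[si]),
                    b_hat, se_q, float(_p2(b_hat / se_q)),
                ))
        qtl_versions[version] = pd.DataFrame(rows, columns=[
            "probe_id", "gene", "probe_chrom", "probe_bp", "snp", "snp_chrom",
            "snp_bp", "freq", "beta_eqtl", "se_eqtl", "p_eqtl"])

    # --- exposure-trait GWAS ---------------------------------------------
    trait_sumstats: dict[str, pd.DataFrame] = {}
    se_t = _se_from_eaf(eaf, cfg.microbiome_n)
    for t, trait in enumerate(trait_names):
        trait_true = np.zeros(n)
        trait_true[inst_idx[t]] = exp_beta[t]
        if rev_causal[t] != 0.0:
            trait_true = trait_true + rev_causal[t] * true_beta
        beta_hat = trait_true + rng.normal(0.0, 1.0, n) * se_t
        z = beta_hat / se_t
        trait_sumstats[trait] = pd.DataFrame({
            "snp": snp_map["snp"], "chrom": snp_map["chrom"],
            "pos": snp_map["pos"], "ea": snp_map["ea"], "oa": snp_map["oa"],
            "eaf": eaf, "beta": beta_hat, "se": se_t, "p": _p2(z),
        })
    trait_truth = pd.DataFrame({
        "trait": trait_names, "forward_beta": fwd_causal,
        "reverse_beta": rev_causal,
        "instruments": [";".join(snp_map["snp"].iloc[inst_idx[t]])
                        for t in range(cfg.n_traits)],
    })

    # --- enrichment contexts, gene sets, PoPS, gene BED -------------------
    # context backgrounds avoid every strong planted signal so the hubs are
    # the only engineered overlap with the pipeline's risk loci
    strong = set(hub_snps) | set(probe_truth["top_snp"])
    pool = snp_map.loc[~snp_map["snp"].isin(strong), "snp"].to_numpy()

    def make_contexts(prefix: str, count: int) -> dict[str, set[str]]:
        out = {}
        for c in range(count):
            background = set(rng.choice(pool, size=cfg.context_size,
                                        replace=False))
            out[f"{prefix}{c + 1}"] = background | set(hub_snps)
        return out

    region_contexts = make_contexts("region", cfg.n_region_contexts)
    cell_contexts = make_contexts("cell", cfg.n_cell_contexts)

    # genes sit just downstream of their top SNP (cis window guaranteed)
    gene_rows = []
    for g in range(cfg.n_genes):
        i = top_idx[g]
        start1 = int(snp_map["pos"].iloc[i]) + 30_000
        gene_rows.append((str(snp_map["chrom"].iloc[i]), start1 - 1,
                          start1 + 20_000, f"ENSG{g + 1:05d}", gene_symbols[g]))
    gene_bed = pd.DataFrame(gene_rows, columns=["chrom", "start0", "end",
                                                "gene_id", "symbol"])

    pops_scores = {}
    for g, sym in enumerate(gene_symbols):
        if g < cfg.n_hubs:
            pops_scores[sym] = 0.95  # known per-window maximum at the hubs
        elif rng.random() < 0.9:
            pops_scores[sym] = float(np.round(rng.normal(0.3, 0.25), 6))

    gene_sets = {}
    set_size = min(cfg.gene_set_size, cfg.n_genes)
    med_genes = [gene_symbols[g] for g in range(cfg.n_mediation_genes)]
    gene_sets["SET_PLANTED"] = med_genes[:set_size]
    for s in range(cfg.n_gene_sets - 1):
        members = rng.choice(gene_symbols, size=set_size, replace=False)
        gene_sets[f"SET{s + 1:02d}"] = sorted(members)

    return SimData(
        config=cfg, snp_map=snp_map, ld=ld, studies=studies,
        snp_truth=snp_truth, qtl_versions=qtl_versions,
        probe_truth=probe_truth, trait_sumstats=trait_sumstats,
        trait_truth=trait_truth, region_contexts=region_contexts,
        cell_contexts=cell_contexts, gene_bed=gene_bed,
        pops_scores=pops_scores, gene_sets=gene_sets, hub_snps=hub_snps,
    )
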