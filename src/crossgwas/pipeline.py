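"""End-to-end orchestration: meta -> loci -> annotate -> enrich/smr/mr -> integrate.

:func:`run_pipeline` drives the full analysis over in-memory inputs (a
:class:`~crossgwas.synthetic.SimData` bundle or equivalently-shaped frames)
and returns every stage table plus a provenance manifest. The CLI in
:mod:`crossgwas.cli` is a thin file-based wrapper around this module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__, annotate, enrich, integrate, loci, mr, smr
from .meta import meta_pipeline
from .synthetic import SimData

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the integrated analysis, with the study defaults."""

    eaf_max_diff: float = 0.2
    fallback_q_p: float = 0.1
    fallback_i2: float = 50.0
    known_db_p: float = 5e-6
    known_db_r2: float = 0.001
    known_db_window_kb: float = 10_000.0
    gwas_sig_p: float = 5e-8
    novelty_dist_kb: float = 500.0
    gene_window_kb: float = 500.0
    p_eqtl_max: float = 5e-8
    bh_alpha: float = 0.05
    presso_n_sim: int = 1000
    genome_background: int = 1_000_000
    seed: int = 0


@dataclass
class PipelineResult:
    meta_table: pd.DataFrame
    known_db: loci.KnownLocusDB
    novel: pd.DataFrame
    annotated: list[annotate.AnnotatedLocus]
    region_enrichment: list[enrich.EnrichmentResult]
    cell_enrichment: list[enrich.EnrichmentResult]
    gmt_enrichment: list[enrich.EnrichmentResult]
    smr_tables: dict[str, pd.DataFrame]
    mr_reports: list[mr.MrReport]
    mr_table: pd.DataFrame
    common: dict[str, set[str]]
    smr_overlap: set[str]
    joint: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta_table.to_csv(out / "meta.tsv", sep="\t", index=False)
        self.known_db.to_table().to_csv(out / "known_loci.tsv", sep="\t",
                                        index=False)
        self.novel.to_csv(out / "novel_loci.tsv", sep="\t", index=False)
        annotate.write_annotation_table(self.annotated,
                                        out / "novel_annotated.tsv")
        enrich.results_table(self.region_enrichment).to_csv(
            out / "enrich_regions.tsv", sep="\t", index=False)
        enrich.results_table(self.cell_enrichment).to_csv(
            out / "enrich_cells.tsv", sep="\t", index=False)
        enrich.results_table(self.gmt_enrichment).to_csv(
            out / "enrich_genesets.tsv", sep="\t", index=False)
        for version, df in self.smr_tables.items():
            df.to_csv(out / f"smr_{version}.tsv", sep="\t", index=False)
        self.mr_table.to_csv(out / "mr_significance.tsv", sep="\t", index=False)
        self.joint.to_csv(out / "joint_report.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _risk_loci(meta_table: pd.DataFrame, ld: loci.LdMatrix,
               params: PipelineParams) -> set[str]:
    clumped = loci.ld_clump(
        meta_table, ld,
        loci.ClumpParams(r2_threshold=params.known_db_r2,
                         window_kb=params.known_db_window_kb,
                         p_threshold=params.gwas_sig_p))
    return {iv.snp_id for iv in clumped}


def _enriched_contexts_by_snp(snps, contexts, results, alpha):
    sig = {r.context for r in results if (r.p_adj or 1.0) < alpha}
    out = {}
    for snp in snps:
        labels = [c for c in sig if snp in contexts[c]]
        if labels:
            out[snp] = labels
    return out


def run_pipeline(data: SimData, params: Optional[PipelineParams] = None
                 ) -> PipelineResult:
    """Run every stage over a simulated (or equivalently shaped) input bundle."""
    params = params or PipelineParams()

    pooled = meta_pipeline(
        data.studies, eaf_max_diff=params.eaf_max_diff,
        fallback_q_p=params.fallback_q_p, fallback_i2=params.fallback_i2)

    db_params = loci.ClumpParams(r2_threshold=params.known_db_r2,
                                 window_kb=params.known_db_window_kb,
                                 p_threshold=params.known_db_p)
    known = loci.build_known_db(data.studies, data.ld, db_params)
    novel = loci.screen_novel(pooled, known, min_dist_kb=params.novelty_dist_kb,
                              p_threshold=params.gwas_sig_p)

    genes = [
        annotate.GeneRecord(str(t.gene_id), str(t.symbol), str(t.chrom),
                            int(t.start0) + 1, int(t.end))
        for t in data.gene_bed.itertuples(index=False)
    ]
    annotated = annotate.annotate_loci(novel, genes, data.pops_scores,
                                       window_kb=params.gene_window_kb)

    risk = _risk_loci(pooled, data.ld, params)
    region_res = enrich.enrich_contexts(risk, data.region_contexts,
                                        params.genome_background)
    cell_res = enrich.enrich_contexts(risk, data.cell_contexts,
                                      params.genome_background)
    window_genes = sorted({g for a in annotated for g in a.all_genes})
    gmt_res = enrich.ora_gmt(window_genes or ["NONE"], data.gene_sets,
                             universe_size=max(len(data.pops_scores),
                                               data.config.n_genes))

    smr_tables = {
        version: smr.smr_scan(pooled, table, p_eqtl_max=params.p_eqtl_max)
        for version, table in data.qtl_versions.items()
    }

    outcome = pooled.rename(columns={"eaf_pooled": "eaf"})
    reports, mr_table = mr.run_bidirectional(
        data.trait_sumstats, outcome, data.ld, outcome_label="disorder",
        reverse_exposure=outcome, reverse_outcomes=data.trait_sumstats,
        seed=params.seed, presso_n_sim=params.presso_n_sim,
        bh_alpha=params.bh_alpha)

    novel_set = set(novel["snp"])
    fwd_snps: set[str] = set()
    rev_snps: set[str] = set()
    for rep in reports:
        if rep.loo is not None:
            snps = set(rep.loo["snp"])
            (fwd_snps if rep.direction == "forward" else rev_snps).update(snps)
    common = integrate.common_snps({"forward": fwd_snps, "reverse": rev_snps},
                                   novel_set)
    smr_overlap = integrate.cross_version_top_overlap(smr_tables,
                                                      fdr_max=params.bh_alpha)

    smr_top_sets = {
        v: set(df.loc[df["FDR_BH"] < params.bh_alpha, "topSNP"])
        for v, df in smr_tables.items()
    }
    smr_union: set[str] = set().union(*smr_top_sets.values()) if smr_top_sets else set()
    all_snps = novel_set | fwd_snps | rev_snps | smr_union
    joint = integrate.joint_report(
        novel_set,
        mr_instruments={"forward": fwd_snps, "reverse": rev_snps},
        smr_top_by_version=smr_top_sets,
        enriched_regions_by_snp=_enriched_contexts_by_snp(
            all_snps, data.region_contexts, region_res, params.bh_alpha),
        enriched_cells_by_snp=_enriched_contexts_by_snp(
            all_snps, data.cell_contexts, cell_res, params.bh_alpha),
        nearest_gene={a.snp_id: a.nearest_gene or "" for a in annotated},
        pops_gene={a.snp_id: a.pops_gene or "" for a in annotated},
    )

    cfg_hash = hashlib.sha256(
        json.dumps(params.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": params.seed,
        "rows": {
            "meta": len(pooled), "known_db": len(known.entries),
            "novel": len(novel),
            "smr": {v: len(df) for v, df in smr_tables.items()},
            "mr_reports": len(reports), "joint": len(joint),
        },
    }
    return PipelineResult(
        meta_table=pooled, known_db=known, novel=novel, annotated=annotated,
        region_enrichment=region_res, cell_enrichment=cell_res,
        gmt_enrichment=gmt_res, smr_tables=smr_tables, mr_reports=reports,
        mr_table=mr_table, common=common, smr_overlap=smr_overlap,
        joint=joint, manifest=manifest)
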