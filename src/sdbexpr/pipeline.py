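"""End-to-end workflow orchestration.

The discovery workflow: per-stratum mixed-model association in each
cohort -> bidirectional cross-replication -> all-pairs meta-analysis ->
union of the two discovery routes -> sign-constrained treatment
replication in the paired cohort -> preranked enrichment of each
trait's transcriptome and the treatment response.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ExpressionStudy, ModelSpec, fit_study
from .enrichment import (GeneSetCollection, build_ranked_list, overlap_edges,
                         permute_and_score)
from .meta import combine_discoveries, meta_analyze, select_meta_genes
from .replication import cross_replicate
from .treatment import PairedStudy, paired_test_all, treatment_replicate
from . import io as sio

logger = logging.getLogger(__name__)

__all__ = ["run_workflow", "run_pipeline", "carried_records"]


def carried_records(cross_records: pd.DataFrame,
                    meta_table: pd.DataFrame,
                    meta_q_threshold: float = 0.05) -> pd.DataFrame:
    """Build the carried-forward (gene, trait, sign) table from both
    discovery routes, one row per distinct discovery record."""
    parts = []
    if not cross_records.empty:
        hit = cross_records[cross_records["pair_replicates"] == True]  # noqa: E712
        parts.append(hit[["gene", "trait", "sign"]])
    if not meta_table.empty:
        hit = meta_table[meta_table["meta_q"] < meta_q_threshold]
        parts.append(hit[["gene", "trait", "sign"]])
    if not parts:
        return pd.DataFrame(columns=["gene", "trait", "sign"])
    out = pd.concat(parts, ignore_index=True).drop_duplicates()
    return out.sort_values(["gene", "trait"]).reset_index(drop=True)


def run_workflow(study_a: ExpressionStudy, study_b: ExpressionStudy,
                 paired: PairedStudy | None = None,
                 genesets: GeneSetCollection | None = None,
                 traits=("AHI", "avgO2", "minO2"),
                 covariates_a=(), covariates_b=(),
                 include_bmi: bool = False,
                 discovery_q: float = 0.05, replication_p: float = 0.05,
                 treatment_p: float = 0.05, enrichment_q: float = 0.05,
                 overlap_coefficient: float = 0.25,
                 n_permutations: int = 1000,
                 seed: int = 0) -> dict:
    """Run the full discovery + treatment + enrichment workflow in
    memory; returns a dict of stage tables plus a JSON-able summary."""
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(len(traits) + 2))
    t0 = time.time()
    results: dict = {"association": {}, "cross_replication": {}, "meta": {}}
    assoc = {}
    for cohort, study, cov in (("A", study_a, covariates_a),
                               ("B", study_b, covariates_b)):
        frames = []
        for trait in traits:
            spec = ModelSpec(trait=trait, covariates=list(cov),
                             include_bmi=include_bmi)
            frames.append(fit_study(study, spec))
        assoc[cohort] = pd.concat(frames, ignore_index=True)
        logger.info("associated cohort %s (%d rows, %.1fs)", cohort,
                    len(assoc[cohort]), time.time() - t0)
    results["association"] = assoc

    cross_genes: set = set()
    cross_records = []
    meta_frames = []
    for trait in traits:
        cr = cross_replicate(assoc["A"], assoc["B"],
                             study_a.transcript_map, study_b.transcript_map,
                             trait, q_threshold=discovery_q,
                             p_threshold=replication_p)
        results["cross_replication"][trait] = cr
        cross_genes |= set(cr.replicated_genes)
        cross_records.append(cr.records)
        meta_frames.append(meta_analyze(assoc["A"], assoc["B"], trait))
    cross_records = pd.concat(cross_records, ignore_index=True)
    meta_table = pd.concat(meta_frames, ignore_index=True)
    meta_gene_list = select_meta_genes(meta_table, q_threshold=discovery_q)
    combined = combine_discoveries(sorted(cross_genes), meta_gene_list)
    results.update(cross_records=cross_records, meta_table=meta_table,
                   combined=combined)

    treatment_table = pd.DataFrame()
    responding: list = []
    if paired is not None and not combined.empty:
        carried = carried_records(cross_records, meta_table, discovery_q)
        treatment_table = treatment_replicate(carried, paired,
                                              p_threshold=treatment_p)
        if not treatment_table.empty:
            responding = sorted(
                treatment_table.loc[treatment_table["gene_responding"] == True,  # noqa: E712
                                    "gene"].unique())
    results["treatment"] = treatment_table
    results["responding_genes"] = responding

    enrichment_tables = {}
    edges = {}
    if genesets is not None:
        for trait in traits:
            rng = np.random.default_rng(next(child))
            ranked = build_ranked_list(
                assoc["A"][assoc["A"]["trait"] == trait], seed=rng)
            enr = permute_and_score(ranked, genesets,
                                    n_perm=n_permutations, seed=rng)
            enrichment_tables[trait] = enr
            if "fdr_q" in enr:
                sig = enr[(enr["fdr_q"] < enrichment_q)
                          & (enr["testable"] == True)]  # noqa: E712
                edges[trait] = overlap_edges(
                    {s: genesets.sets[s] for s in sig["set"]},
                    threshold=overlap_coefficient)
        if paired is not None:
            rng = np.random.default_rng(next(child))
            ranked = build_ranked_list(paired_test_all(paired), seed=rng,
                                       stat_col="t")
            enrichment_tables["treatment"] = permute_and_score(
                ranked, genesets, n_perm=n_permutations, seed=rng)
    results["enrichment"] = enrichment_tables
    results["enrichment_edges"] = edges

    results["summary"] = {
        "seed": seed,
        "traits": list(traits),
        "thresholds": {"discovery_q": discovery_q,
                       "replication_p": replication_p,
                       "treatment_p": treatment_p,
                       "enrichment_q": enrichment_q,
                       "overlap_coefficient": overlap_coefficient},
        "n_transcripts": {c: int(assoc[c]["transcript"].nunique())
                          for c in assoc},
        "n_cross_replicated_genes": len(cross_genes),
        "n_meta_genes": len(meta_gene_list),
        "n_combined_genes": int(len(combined)),
        "n_meta_only_genes": int((combined["route"] == "meta-only").sum()),
        "n_responding_genes": len(responding),
        "n_significant_sets": {k: int((v["fdr_q"] < enrichment_q).sum())
                               for k, v in enrichment_tables.items()
                               if "fdr_q" in v},
        "runtime_s": round(time.time() - t0, 2),
    }
    return results


def run_pipeline(config: sio.PipelineConfig) -> dict:
    """File-based entry point: load configured inputs, run the workflow,
    write every stage table and a JSON summary under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study_a = sio.load_expression_study("A", **config.cohort_a)
    study_b = sio.load_expression_study("B", **config.cohort_b)
    paired = None
    if config.paired:
        pre = sio.read_expression(config.paired["pre"])
        post = sio.read_expression(config.paired["post"])
        paired = PairedStudy(expr_pre=pre, expr_post=post)
    genesets = sio.read_gmt(config.gene_sets) if config.gene_sets else None
    results = run_workflow(
        study_a, study_b, paired, genesets,
        traits=config.traits,
        covariates_a=config.covariates_a, covariates_b=config.covariates_b,
        include_bmi=config.include_bmi,
        discovery_q=config.discovery_q, replication_p=config.replication_p,
        treatment_p=config.treatment_p, enrichment_q=config.enrichment_q,
        overlap_coefficient=config.overlap_coefficient,
        n_permutations=config.n_permutations, seed=config.seed)
    th = config.thresholds()
    for cohort, table in results["association"].items():
        sio.write_table(table, out / f"association_{cohort}.tsv",
                        seed=config.seed, thresholds=th)
    sio.write_table(results["cross_records"], out / "cross_replication.tsv",
                    seed=config.seed, thresholds=th)
    sio.write_table(results["meta_table"], out / "meta_analysis.tsv",
                    seed=config.seed, thresholds=th)
    sio.write_table(results["combined"], out / "combined_genes.tsv",
                    seed=config.seed, thresholds=th)
    if not results["treatment"].empty:
        sio.write_table(results["treatment"], out / "treatment.tsv",
                        seed=config.seed, thresholds=th)
    for key, table in results["enrichment"].items():
        sio.write_table(table, out / f"enrichment_{key}.tsv",
                        seed=config.seed, thresholds=th)
    for key, table in results["enrichment_edges"].items():
        sio.write_table(table, out / f"enrichment_edges_{key}.tsv",
                        seed=config.seed, thresholds=th)
    with open(out / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2, sort_keys=True)
    return results
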