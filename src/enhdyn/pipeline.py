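"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` executes the full analysis in stage order — simulate,
call enhancers, quantify, test differential expression, cluster, call
interactions, network dynamics, GWAS enrichment, characterization — and
returns a self-consistent run report (all percentages stored with their
integer numerators/denominators).  Deterministic for a given config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from enhdyn import enhancers as enh_mod
from enhdyn import enrichment as enr_mod
from enhdyn import expression as expr_mod
from enhdyn import interactions as ia_mod
from enhdyn import report as report_mod
from enhdyn.io import TIMEPOINTS
from enhdyn.regions import GenomicRegion, frame_to_regions
from enhdyn.simulate import (
    SimulatedData,
    SimulationConfig,
    hic_samples,
    simulate_all,
)

PROMOTER_LOG2CPM_MIN = -2.0
ENHANCER_LOG2CPM_MIN = -2.5


def _tp_mean_expression(log2_cpm: pd.DataFrame, samples) -> pd.DataFrame:
    """Average log2 CPM over replicates per timepoint."""
    cols = {}
    for t in TIMEPOINTS:
        sids = [s.sample_id for s in samples if s.timepoint == t
                and s.sample_id in log2_cpm.columns]
        if sids:
            cols[t] = log2_cpm[sids].mean(axis=1)
    return pd.DataFrame(cols)


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    n_permutations: int = 200,
    min_neighbors: int = 200,
    write_inputs: bool = False,
) -> dict[str, Any]:
    """Run every stage on a fresh synthetic landscape; return the run report."""
    report: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": report_mod.config_hash(dataclasses.asdict(config)),
        "stages": {},
        "manifest": [],
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    data: SimulatedData = simulate_all(
        config, outdir / "inputs" if (outdir and write_inputs) else None)
    truth = data.truth
    prom_regions = truth.promoter_regions()
    enh_regions = truth.enhancer_regions()
    report["stages"]["simulate"] = {
        "n_promoters": len(truth.promoters),
        "n_enhancers": len(truth.enhancers),
        "n_ctss_samples": len(data.ctss),
        "n_hic_samples": len(data.hic),
        "n_variants": len(data.variants),
    }

    # -- enhancer calling (nascent libraries) ------------------------------
    nascent = [s.sample_id for s in data.samples if s.assay == "nascent"]
    pooled = enh_mod.pool_ctss([data.ctss[s] for s in nascent])
    clusters = enh_mod.cluster_ctss(pooled)
    loci = enh_mod.call_bidirectional(clusters, promoter_mask=prom_regions)
    novelty = enh_mod.classify_novelty(loci, {"known": truth.known_enhancers})
    n_known_loci = int((novelty["novelty"] == "known").sum())
    report["stages"]["call_enhancers"] = {
        "n_tag_clusters": len(clusters),
        "n_bidirectional_loci": len(loci),
        "n_known_loci": n_known_loci,
        "n_novel_loci": len(loci) - n_known_loci,
    }

    # -- quantification / DE / clustering ----------------------------------
    total_ids = [s.sample_id for s in data.samples if s.assay == "total"]
    prom_counts = expr_mod.count_tags(
        {s: data.ctss[s] for s in total_ids}, prom_regions, strand_specific=True)
    enh_counts = expr_mod.count_tags(
        {s: data.ctss[s] for s in nascent}, enh_regions, strand_specific=True)
    prom_expr = expr_mod.cpm_normalize(prom_counts)
    enh_expr = expr_mod.cpm_normalize(enh_counts)
    prom_keep = expr_mod.filter_expressed(prom_expr, PROMOTER_LOG2CPM_MIN)
    enh_keep = expr_mod.filter_expressed(enh_expr, ENHANCER_LOG2CPM_MIN)
    n_novel_retained = int(
        truth.enhancers.set_index("id").loc[enh_keep, "novel"].sum())

    sample_meta = {s.sample_id: s for s in data.samples}
    de_results, clusters_by_kind, keep_by_kind = {}, {}, {}
    for kind, counts, keep, sids in (
        ("promoter", prom_counts, prom_keep, total_ids),
        ("enhancer", enh_counts, enh_keep, nascent),
    ):
        sub = counts.loc[keep, sids]
        groups = [sample_meta[s].timepoint for s in sids]
        de = expr_mod.de_test(sub, groups)
        de_results[kind] = de
        keep_by_kind[kind] = keep
        de_ids = list(de.index[de["is_de"]])
        expr = expr_mod.cpm_normalize(sub).log2_cpm
        if len(de_ids) >= 4:
            cl = expr_mod.cluster_temporal(
                expr.loc[de_ids], [sample_meta[s] for s in sids],
                seed=config.seed)
        else:
            cl = pd.DataFrame(columns=["cluster"])
        clusters_by_kind[kind] = cl

    nearest = expr_mod.nearest_promoter(
        [r for r in enh_regions if r.id in set(enh_keep)], prom_regions)
    overlap_matrix = expr_mod.cluster_overlap_matrix(
        clusters_by_kind["enhancer"]["cluster"].to_dict(),
        clusters_by_kind["promoter"]["cluster"].to_dict(),
        nearest)
    report["stages"]["expression"] = {
        "n_promoters_retained": len(prom_keep),
        "n_enhancers_retained": len(enh_keep),
        "n_de_promoters": int(de_results["promoter"]["is_de"].sum()),
        "n_de_enhancers": int(de_results["enhancer"]["is_de"].sum()),
        "cluster_sizes": {
            kind: cl["cluster"].value_counts().sort_index().to_dict()
            for kind, cl in clusters_by_kind.items()
        },
    }

    # -- interaction calling ------------------------------------------------
    probes = truth.probes
    neg = probes[probes["probe_class"] == "negative_control"]
    support, backgrounds = {}, {}
    for t, r in hic_samples(config):
        sup = ia_mod.bin_pairs(data.hic[f"hic_{t}_r{r}"], probes,
                               bin_size=config.hic_bin_size,
                               max_distance=config.hic_max_distance)
        support[(t, r)] = sup
        backgrounds[(t, r)] = ia_mod.fit_background(
            sup, neg, truth.chrom_sizes, bin_size=config.hic_bin_size,
            max_distance=config.hic_max_distance)

    reps = sorted({r for _, r in support})
    calls = []
    for t in TIMEPOINTS:
        calls.append(ia_mod.call_interactions(
            {r: support[(t, r)] for r in reps},
            {r: backgrounds[(t, r)] for r in reps},
            probes, timepoint=t, bin_size=config.hic_bin_size))
    calls = pd.concat(calls, ignore_index=True)
    passing = calls[calls["passes"]]
    probe_class = dict(zip(probes["id"], probes["probe_class"]))
    stats_summary = ia_mod.interaction_stats(calls, probe_class)
    nearest_frac = ia_mod.nearest_gene_fraction(
        calls, prom_regions, bin_size=config.hic_bin_size)

    # interaction-frequency enrichment of targets over negative controls:
    # support-filtered candidate slots per total testable slots, per class
    anchor_cls = calls["anchor_id"].map(probe_class)
    is_neg = anchor_cls == "negative_control"
    target_anchors = probes[probes["probe_class"] != "negative_control"]
    slots_t = ia_mod.total_candidate_slots(
        target_anchors, truth.chrom_sizes, config.hic_bin_size,
        config.hic_max_distance) * len(TIMEPOINTS)
    slots_n = ia_mod.total_candidate_slots(
        neg, truth.chrom_sizes, config.hic_bin_size,
        config.hic_max_distance) * len(TIMEPOINTS)
    fold, fold_p = (float("nan"), float("nan"))
    calls_fold = float("nan")
    if slots_n > 0 and slots_t > 0:
        fold, fold_p = ia_mod.enrichment_vs_negative(
            int((~is_neg).sum()), slots_t, int(is_neg.sum()), slots_n)
        # significant calls per candidate slot, targets over negatives
        n_pass_t = int((passing["anchor_id"].map(probe_class)
                        != "negative_control").sum())
        n_pass_n = int(len(passing)) - n_pass_t
        if n_pass_t or n_pass_n:
            with np.errstate(divide="ignore"):
                calls_fold = ((n_pass_t / slots_t) / (n_pass_n / slots_n)
                              if n_pass_n else float("inf"))

    # -- networks and dynamics ---------------------------------------------
    features = prom_regions + enh_regions
    annotated = ia_mod.map_bins_to_features(calls, features,
                                            bin_size=config.hic_bin_size)
    networks = {t: ia_mod.build_network(annotated, t) for t in TIMEPOINTS}
    de_prom = set(de_results["promoter"].index[de_results["promoter"]["is_de"]])
    de_enh = set(de_results["enhancer"].index[de_results["enhancer"]["is_de"]])
    prom_ids = set(truth.promoters["id"])
    dynamics, de_compare = {}, {}
    for ta, tb in (("D1", "D3"), ("D1", "D6"), ("D3", "D6")):
        dyn = ia_mod.all_node_dynamics(networks[ta], networks[tb])
        dyn_prom = dyn[dyn.index.isin(prom_ids)]
        dynamics[f"{ta}_vs_{tb}"] = dyn
        if len(dyn_prom):
            labels = {n: (n in de_prom) for n in dyn_prom.index}
            try:
                stat, p = ia_mod.compare_de_dynamics(dyn_prom, labels)
                de_compare[f"{ta}_vs_{tb}"] = {"statistic": stat, "p": p}
            except ValueError:
                de_compare[f"{ta}_vs_{tb}"] = None

    # interaction involvement counts
    n_interactions = int(len(passing))
    de_features = de_prom | de_enh
    other_nodes = annotated.loc[passing.index, "other_nodes"]
    involved = passing["anchor_id"].isin(de_features).to_numpy()
    if len(passing):
        involved = involved | np.array(
            [any(n in de_features for n in nodes) for nodes in other_nodes],
            dtype=bool)
    interacting_anchors = set(passing["anchor_id"])
    for nodes in other_nodes:
        interacting_anchors.update(nodes)
    enh_anchor_ids = set(probes.loc[probes["probe_class"].isin(["enhancer", "gwas"]),
                                    "id"])
    de_enh_targeted = de_enh & enh_anchor_ids
    gwas_anchor_ids = set(probes.loc[probes["probe_class"] == "gwas", "id"])

    report["stages"]["interactions"] = {
        "n_candidate_slots": int(len(calls)),
        "n_interactions": n_interactions,
        "mean_distance": stats_summary["mean_distance"],
        "frac_gt_100kb": stats_summary["frac_gt_100kb"],
        "per_class": stats_summary["per_class"],
        "nearest_gene_fraction": None if nearest_frac != nearest_frac
        else nearest_frac,
        "target_vs_negative_fold": None if fold != fold else fold,
        "target_vs_negative_p": None if fold_p != fold_p else fold_p,
        "calls_target_vs_negative_fold": None if calls_fold != calls_fold
        else calls_fold,
        "de_dynamics": de_compare,
    }

    # -- GWAS enrichment ----------------------------------------------------
    enh_catalog = enh_regions
    cov = enr_mod.snp_covariates(data.variants, data.ld, prom_regions)
    pm = enr_mod.proxy_map(data.gwas_snps, data.ld)
    loci_gwas = enr_mod.ld_expand(data.gwas_snps, data.ld)
    controls = enr_mod.match_controls(
        data.gwas_snps, cov, pm,
        min_neighbors=min(min_neighbors, max(1, len(cov) // 4)))
    enr = enr_mod.enrichment_test(
        loci_gwas, enh_catalog, controls, data.variants, data.ld,
        n_permutations=n_permutations, seed=config.seed)
    report["stages"]["gwas_enrichment"] = {
        "n_loci": enr.n_loci, "observed": enr.observed,
        "expected": enr.expected, "fold": enr.fold, "p": enr.p,
    }

    # -- characterization of novel enhancers --------------------------------
    novel_ids = set(truth.enhancers.loc[truth.enhancers["novel"], "id"])
    novel_regions = [r for r in enh_regions if r.id in novel_ids]
    random_regions = enr_mod.sample_matched_regions(
        novel_regions, truth.chrom_sizes, seed=config.seed)
    cons = enr_mod.conservation_compare(
        novel_regions, {"random": random_regions}, data.conservation)
    profiles = enr_mod.nucleotide_diversity(novel_regions, data.variants)
    rand_profiles = enr_mod.nucleotide_diversity(random_regions, data.variants)
    region_snps = enr_mod._snps_in_regions(data.variants, novel_regions)
    random_snps = enr_mod._snps_in_regions(data.variants, random_regions)
    eqtl_fold, eqtl_p = enr_mod.eqtl_enrichment(
        list(region_snps.index[region_snps]), data.eqtl_snps,
        list(random_snps.index[random_snps])) \
        if random_snps.any() else (float("nan"), float("nan"))
    report["stages"]["characterize"] = {
        "n_novel_regions": len(novel_regions),
        "conservation_mean_novel": float(cons.loc["template", "mean_score"]),
        "conservation_mean_random": float(cons.loc["random", "mean_score"]),
        "conservation_p": float(cons.loc["random", "p"]),
        "mean_pi_novel": float(profiles["mean_pi"].mean()),
        "mean_pi_random": float(rand_profiles["mean_pi"].mean()),
        "snps_per_region_novel": float(profiles["n_snps"].mean()),
        "snps_per_region_random": float(rand_profiles["n_snps"].mean()),
        "eqtl_fold": eqtl_fold, "eqtl_p": eqtl_p,
    }

    # -- headline ratios -----------------------------------------------------
    report["headline"] = {
        **report_mod.summarize_universe(
            [len(truth.known_enhancers)], len(loci), n_known_loci,
            len(enh_keep), n_novel_retained),
        **report_mod.summarize_interactions(
            n_interactions, int(involved.sum()),
            len(de_enh), len(de_enh_targeted & interacting_anchors),
            len(gwas_anchor_ids),
            len(gwas_anchor_ids & interacting_anchors)),
    }
    report_mod.validate_report(report["headline"])

    if outdir is not None:
        enh_mod.loci_to_frame(loci).to_csv(outdir / "loci.tsv", sep="\t",
                                           index=False)
        calls.drop(columns="other_nodes", errors="ignore").to_csv(
            outdir / "interaction_calls.tsv", sep="\t", index=False)
        for name, dyn in dynamics.items():
            dyn.to_csv(outdir / f"dynamics_{name}.tsv", sep="\t")
        overlap_matrix.to_csv(outdir / "cluster_overlap_matrix.tsv", sep="\t")
        report["manifest"] = sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file())
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
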