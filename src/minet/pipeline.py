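"""End-to-end orchestration of the five-phase workflow.

``run_all`` executes synthesis (or loads user inputs), preprocessing,
cis eQTL mapping, target lookup, PPI expansion, the fused multitask
fit and network integration, writing every stage table plus SIF/GraphML
exports and a summary JSON of the counts each phase produced.  All
randomness flows from a single seed, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from minet import eqtl, integrate, io, mtlasso, ppi, preprocess, synth, targets

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "synth": {},
    "preprocess": {},
    "eqtl": {"window": eqtl.DEFAULT_WINDOW, "fdr": eqtl.DEFAULT_FDR},
    "targets": {"ambiguous_fraction": 0.25},
    "ppi": {"permutations": ppi.DEFAULT_PERMUTATIONS, "alpha": ppi.DEFAULT_ALPHA},
    "mtlasso": {},
    "integrate": {},
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def run_all(config: dict | None, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the complete workflow; returns the summary dict it also writes.

    ``seed`` overrides ``config["seed"]`` and drives the synthetic
    cohort, the permutation null and cross-validation splits alike.
    """
    config = _merge_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    master_seed = int(config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": master_seed}

    # --- inputs: synthetic cohort with ground truth -------------------
    synth_cfg = synth.SynthConfig(**{**config["synth"], "seed": master_seed})
    inputs = outdir / "inputs"
    truth = synth.generate_all(
        synth_cfg,
        inputs,
        ambiguous_fraction=float(config["targets"]["ambiguous_fraction"]),
    )
    mirna_raw = io.read_expression_tsv(inputs / "mirna_expression.tsv")
    gene_raw = io.read_expression_tsv(inputs / "gene_expression.tsv")
    mirna_bed = io.read_bed(inputs / "mirnas.bed")
    gene_bed = io.read_bed(inputs / "genes.bed")
    target_db = io.read_target_db(inputs / "targets.tsv")
    ppi_net = io.read_ppi(inputs / "ppi.tsv")
    summary["inputs"] = {
        "n_samples": synth_cfg.n_samples,
        "n_mirnas": synth_cfg.n_mirnas,
        "n_genes": synth_cfg.n_genes,
        "n_true_eqtls": len(truth.true_eqtl_pairs),
        "ppi_edges": ppi_net.number_of_edges(),
    }

    # --- preprocessing ------------------------------------------------
    mirna_raw, gene_raw = preprocess.drop_incomplete_samples(mirna_raw, gene_raw)
    mirna_norm = preprocess.quantile_normalize(mirna_raw)
    gene_norm = preprocess.quantile_normalize(gene_raw)
    io.write_expression_tsv(mirna_norm, outdir / "mirna_normalized.tsv")
    io.write_expression_tsv(gene_norm, outdir / "gene_normalized.tsv")

    # --- cis eQTL scan ------------------------------------------------
    eqtl_table = eqtl.call_eqtls(
        mirna_norm,
        gene_norm,
        mirna_bed,
        gene_bed,
        window=int(config["eqtl"]["window"]),
        fdr_cutoff=float(config["eqtl"]["fdr"]),
    )
    eqtl_table.to_csv(outdir / "eqtl_table.tsv", sep="\t", index=False, float_format="%.10g")
    seed_rows = eqtl_table[eqtl_table["is_seed"]] if not eqtl_table.empty else eqtl_table
    seed_mirnas = sorted(set(seed_rows["mirna_id"])) if not seed_rows.empty else []
    perturbed_genes = sorted(set(seed_rows["gene_id"])) if not seed_rows.empty else []
    summary["eqtl"] = {
        "tested_pairs": int(len(eqtl_table)),
        "seed_eqtls": int(len(seed_rows)),
        "unique_seed_mirnas": len(seed_mirnas),
        "unique_perturbed_genes": len(perturbed_genes),
    }
    logger.info(
        "eQTL scan: %d pairs tested, %d seeds (%d miRNAs, %d genes)",
        len(eqtl_table), len(seed_rows), len(seed_mirnas), len(perturbed_genes),
    )

    # --- target lookup ------------------------------------------------
    interactions = targets.lookup_targets(seed_mirnas, target_db, set(gene_norm.index))
    interactions.to_csv(outdir / "target_interactions.tsv", sep="\t", index=False)
    target_genes = sorted(set(interactions["gene_id"]))
    summary["targets"] = {
        "interactions": int(len(interactions)),
        "unique_target_genes": len(target_genes),
        "targets_in_expression": int(interactions["in_gene_universe"].sum())
        if not interactions.empty
        else 0,
    }

    # --- PPI expansion -------------------------------------------------
    seed_genes = sorted(set(perturbed_genes) | set(target_genes))
    rng = np.random.default_rng(master_seed + 101)
    scores = ppi.score_seeds(
        set(seed_genes), ppi_net, n_perm=int(config["ppi"]["permutations"]), rng=rng
    )
    scores.to_csv(outdir / "seed_scores.tsv", sep="\t", index=False, float_format="%.10g")
    direct = ppi.direct_network(set(seed_genes), ppi_net)
    expansion = ppi.expand(
        set(seed_genes), ppi_net, scores, alpha=float(config["ppi"]["alpha"])
    )
    pd.DataFrame(expansion, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "ppi_expansion.tsv", sep="\t", index=False
    )
    summary["ppi"] = {
        "seed_genes": len(seed_genes),
        "seeds_in_network": int(len(scores)),
        "direct_connections": len(direct),
        "significant_seeds": int((scores["p_corrected"] <= config["ppi"]["alpha"]).sum())
        if not scores.empty
        else 0,
        "selected_interactions": len(expansion),
    }
    logger.info(
        "PPI expansion: %d direct connections, %d selected interactions",
        len(direct), len(expansion),
    )

    # --- fused multitask model -----------------------------------------
    mt_cfg = mtlasso.MtLassoConfig(**{**config["mtlasso"], "cv_seed": master_seed + 202})
    g_gene = mtlasso.build_correlation_graph(gene_norm, mt_cfg.corr_threshold)
    g_mirna = mtlasso.build_correlation_graph(mirna_norm, mt_cfg.corr_threshold)
    b_matrix, fit_info = mtlasso.fit(
        mirna_norm, gene_norm, mt_cfg, g_gene=g_gene, g_mirna=g_mirna
    )
    io.write_expression_tsv(b_matrix, outdir / "mtlasso_coefficients.tsv")
    mt_eqtls = mtlasso.extract_eqtls(b_matrix, mt_cfg)
    mt_eqtls.to_csv(outdir / "mtlasso_eqtls.tsv", sep="\t", index=False, float_format="%.10g")
    mirna_corr, gene_corr = mtlasso.association_subnetworks(
        b_matrix, g_gene, g_mirna, mt_cfg
    )
    pd.DataFrame(mirna_corr, columns=["a", "b", "r"]).to_csv(
        outdir / "mirna_corr_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(gene_corr, columns=["a", "b", "r"]).to_csv(
        outdir / "gene_corr_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
    summary["mtlasso"] = {
        "lambda": fit_info["lam"],
        "gamma1": fit_info["gamma1"],
        "gamma2": fit_info["gamma2"],
        "n_iter": fit_info["n_iter"],
        "eqtls": int(len(mt_eqtls)),
        "mirna_corr_edges": len(mirna_corr),
        "gene_corr_edges": len(gene_corr),
    }

    # --- integration ----------------------------------------------------
    net = integrate.assemble_initial(seed_rows, interactions, expansion)
    initial_nodes, initial_edges = net.number_of_nodes(), net.number_of_edges()
    net = integrate.merge_mirna_correlations(net, mirna_corr)
    added_mirna_corr = net.number_of_edges() - initial_edges
    before = net.number_of_edges()
    net = integrate.merge_gene_correlations(net, gene_corr)
    added_gene_corr = net.number_of_edges() - before
    before = net.number_of_edges()
    net = integrate.merge_mtlasso_eqtls(net, mt_eqtls)
    added_mtlasso = net.number_of_edges() - before
    integrate.export(net, outdir / "integrated_network.sif", "sif")
    integrate.export(net, outdir / "integrated_network.graphml", "graphml")
    integrate.export(net, outdir / "integrated_edges.tsv", "tsv")
    summary["integrate"] = {
        "initial_nodes": initial_nodes,
        "initial_edges": initial_edges,
        "mirna_corr_added": added_mirna_corr,
        "gene_corr_added": added_gene_corr,
        "mtlasso_eqtls_added": added_mtlasso,
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
    }
    logger.info(
        "integrated network: %d nodes, %d edges",
        net.number_of_nodes(), net.number_of_edges(),
    )

    # --- annotation against ground truth -------------------------------
    gene_lists = {"true_perturbed_genes": sorted({g for _, g in truth.true_eqtl_pairs})}
    mirna_lists = {"true_eqtl_mirnas": sorted({m for m, _ in truth.true_eqtl_pairs})}
    report = integrate.annotate_components(
        {"integrated": net}, gene_lists, mirna_lists
    )
    report.to_csv(outdir / "annotation_report.tsv", sep="\t", index=False)
    summary["annotation"] = {
        row.list_name: int(row.overlap_count) for row in report.itertuples(index=False)
    }

    # ground-truth recovery diagnostics
    flagged = (
        set(zip(seed_rows["mirna_id"], seed_rows["gene_id"]))
        if not seed_rows.empty
        else set()
    )
    cis_truth = _cis_true_pairs(truth, mirna_bed, gene_bed, int(config["eqtl"]["window"]))
    summary["recovery"] = {
        "true_cis_pairs": len(cis_truth),
        "true_cis_recovered": len(flagged & cis_truth),
        "false_seed_pairs": len(flagged - truth.true_eqtl_pairs),
    }

    io.write_json(summary, outdir / "summary.json")
    return summary


def _cis_true_pairs(
    truth: synth.GroundTruth,
    mirna_bed: pd.DataFrame,
    gene_bed: pd.DataFrame,
    window: int,
) -> set[tuple[str, str]]:
    cis = set(eqtl.cis_pairs(mirna_bed, gene_bed, window))
    return truth.true_eqtl_pairs & cis
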