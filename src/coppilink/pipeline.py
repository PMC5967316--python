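"""End-to-end orchestration: inputs -> gene sets -> CoPPIs -> statistics ->
subnetworks -> machine-readable summary.

Every stage is a pure function of (inputs, config); identical seeds give
byte-identical output bundles. Stage failures abort with the stage name.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coppi as coppi_mod
from . import expression as expr_mod
from . import genesets as gs_mod
from . import io
from . import netstats as ns_mod
from . import subnetwork as sn_mod
from . import synthetic as syn_mod
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage_seed(base_seed: int, stage: int, extra: int = 0) -> int:
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, stage, extra])
    return int(ss.generate_state(1)[0] % 2**31)


def _load_inputs(config: PipelineConfig, outdir: Path):
    paths = config.inputs
    required = ("edges", "expression_dir", "dnm", "gwas", "annotation")
    if paths:
        for key in required:
            if key not in paths:
                raise PipelineError("load", f"missing input path '{key}'")
        try:
            network = io.read_edge_list(paths["edges"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("load_network", exc) from exc
        try:
            panel = expr_mod.ExpressionPanel.read(paths["expression_dir"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("expression", exc) from exc
        try:
            dnm_table = io.read_dnm_table(paths["dnm"])
            gwas = io.read_gwas_table(paths["gwas"])
            ann = io.read_gene_annotation(paths["annotation"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("variant_tables", exc) from exc
        return network, panel, dnm_table, gwas, ann
    try:
        bundle = syn_mod.generate_all(config.synthetic)
        syn_mod.write_bundle(bundle, outdir / "inputs")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synthesize", exc) from exc
    return (bundle.network, bundle.panel, bundle.dnm_table,
            bundle.gwas_table, bundle.annotation)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    summary: dict = {"config": config.to_dict(), "stages": []}
    manifest: list[str] = []

    network, panel, dnm_table, gwas, ann = _load_inputs(config, outdir)
    summary["network"] = {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
    }
    summary["stages"].append("inputs")

    # --- expression calls ---------------------------------------------------
    try:
        calls = expr_mod.panel_calls(panel, thr.rpkm, thr.min_samples)
        means = expr_mod.site_mean_expression(panel)
        zmat = expr_mod.tissue_z_matrix(means)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", exc) from exc
    calls.to_csv(outdir / "expression_calls.tsv", sep="\t",
                 index_label="gene")
    zmat.to_csv(outdir / "tissue_z.tsv", sep="\t", index_label="gene",
                float_format="%.6g")
    manifest += ["expression_calls.tsv", "tissue_z.tsv"]
    summary["stages"].append("expression")

    # --- gene sets ----------------------------------------------------------
    try:
        dnm = gs_mod.select_dnm_genes(dnm_table, calls, thr.p_dnm)
        cv = gs_mod.map_variants_to_genes(gwas, ann, calls, thr.p_gwas,
                                          thr.window)
        k = min(7, max(1, len(cv)))
        subgroups = gs_mod.partition_cv_subgroups(cv, k) if len(cv) else []
        dnm_ex, cv_ex, shared = gs_mod.resolve_overlap(dnm, cv,
                                                       "exclude_shared")
        seeds = gs_mod.union_geneset(dnm, cv)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("gene_sets", exc) from exc
    gs_mod.write_gene_sets([dnm, cv, *subgroups], outdir / "gene_sets.tsv")
    manifest.append("gene_sets.tsv")
    shared_in_network = sorted(set(shared) & set(network.nodes))
    summary["gene_sets"] = {
        "n_dnm": len(dnm),
        "n_cv": len(cv),
        "n_shared": len(shared),
        "n_shared_in_network": len(shared_in_network),
        "n_seeds": len(seeds),
        "n_dnm_in_network": len(dnm.genes & set(network.nodes)),
        "n_cv_in_network": len(cv.genes & set(network.nodes)),
        "cv_subgroup_sizes": [len(g) for g in subgroups],
    }
    summary["stages"].append("gene_sets")

    # --- expression summaries ----------------------------------------------
    try:
        expr_summary = expr_mod.group_expression_summary([dnm, cv], calls)
        tissue_stats = expr_mod.compare_tissue_specificity(zmat, [dnm, cv])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression_summary", exc) from exc
    io.write_table(expr_summary, outdir / "expression_summary.tsv")
    io.write_table(tissue_stats, outdir / "tissue_specificity_tests.tsv")
    manifest += ["expression_summary.tsv", "tissue_specificity_tests.tsv"]
    summary["stages"].append("expression_summary")

    # --- CoPPIs -------------------------------------------------------------
    coppis: dict = {}
    try:
        for site, matrix in panel.sites.items():
            coppis[site] = coppi_mod.build_coppi(
                network, matrix, calls[site], site
            )
            coppi_mod.write_coppi(
                coppis[site], outdir / f"coppi_{site}.tsv"
            )
            manifest.append(f"coppi_{site}.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coppi", exc) from exc
    summary["coppi"] = {
        site: {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
        for site, g in coppis.items()
    }
    summary["stages"].append("coppi")

    # --- network statistics -------------------------------------------------
    try:
        metrics = ns_mod.node_metrics(
            network, betweenness=config.compute_betweenness
        )
        cols = (
            ("degree", "log_betweenness")
            if config.compute_betweenness else ("degree",)
        )
        comparison = ns_mod.group_comparison(metrics, [dnm_ex, cv_ex], cols)
        rand_results = {}
        for label, gs in (("DNM", dnm_ex), ("CV", cv_ex)):
            members = sorted(gs.genes & set(network.nodes))
            if len(members) < 2:
                continue
            for col_i, col in enumerate(cols):
                stat = ns_mod.make_metric_stat(metrics, col)
                res = ns_mod.empirical_p(
                    stat, members, network, n_draws=thr.n_perm,
                    matching="plain",
                    rng_seed=_stage_seed(config.rng_seed, 10, col_i),
                )
                rand_results[f"{label}_mean_{col}_plain"] = res
            for matching in ("plain", "degree_quartile"):
                res = ns_mod.empirical_p(
                    ns_mod.within_set_edge_count, members, network,
                    n_draws=thr.n_perm, matching=matching,
                    rng_seed=_stage_seed(config.rng_seed, 11,
                                         int(matching == "plain")),
                )
                rand_results[f"{label}_edges_{matching}"] = res
        a = sorted(dnm_ex.genes & set(network.nodes))
        b = sorted(cv_ex.genes & set(network.nodes))
        if len(a) >= 2 and len(b) >= 2:
            for matching in ("plain", "degree_quartile"):
                res = ns_mod.empirical_p_pair(
                    ns_mod.cross_edge_count, a, b, network,
                    n_draws=thr.n_perm, matching=matching,
                    rng_seed=_stage_seed(config.rng_seed, 12,
                                         int(matching == "plain")),
                )
                rand_results[f"DNM_CV_cross_edges_{matching}"] = res
        edge_tests = ns_mod.edge_coexpression_tests(coppis, dnm, cv)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("netstats", exc) from exc
    metrics.to_csv(outdir / "node_metrics.tsv", sep="\t",
                   float_format="%.10g")
    io.write_table(comparison, outdir / "group_comparison.tsv")
    io.write_table(edge_tests, outdir / "edge_coexpression_tests.tsv")
    manifest += ["node_metrics.tsv", "group_comparison.tsv",
                 "edge_coexpression_tests.tsv"]
    rand_json = {
        name: {
            "observed": res.observed,
            "p": res.p,
            "n_draws": res.n_draws,
            "rng_seed": res.rng_seed,
            "matching": res.matching,
            "null_mean": float(np.mean(res.null)),
        }
        for name, res in rand_results.items()
    }
    with open(outdir / "randomization.json", "w") as fh:
        json.dump(rand_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.append("randomization.json")
    summary["netstats"] = {
        "group_comparison": comparison.to_dict(orient="records"),
        "randomization": rand_json,
    }
    summary["stages"].append("netstats")

    # --- subnetworks --------------------------------------------------------
    subnetworks: dict = {}
    baselines: dict = {}
    try:
        seed_genes = seeds.sorted_genes
        for i, (site, cop) in enumerate(sorted(coppis.items())):
            sub = sn_mod.build_subnetwork(
                cop, seed_genes, thr.r1, thr.r2, thr.stop, site_id=site
            )
            subnetworks[site] = sub
            sn_mod.write_subnetwork(
                sub, outdir / "subnetworks", dnm.genes, cv.genes,
                prefix=f"{site}",
            )
            base = sn_mod.random_seed_baseline(
                cop, n_seeds=len(set(seed_genes) & set(cop.nodes)),
                n_runs=thr.n_baseline,
                rng_seed=_stage_seed(config.rng_seed, 20, i),
                r1_min=thr.r1, r2_min=thr.r2, stop_ratio=thr.stop,
            )
            baselines[site] = base
        cross = (
            sn_mod.cross_site_comparison(subnetworks)
            if len(subnetworks) >= 2 else None
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("subnetwork", exc) from exc
    with open(outdir / "baselines.json", "w") as fh:
        json.dump(baselines, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.append("baselines.json")
    summary["subnetworks"] = {
        site: {
            "n_linked": sub.n_linked,
            "n_seeds_in_coppi": len(sub.seed_genes),
            "n_linkers": len(sub.linker_genes),
            "r3": sub.r3,
            "mean_edge_weight": sub.mean_edge_weight,
            "s": sub.s,
            "n_baselines_dominated": sum(
                sn_mod.pareto_dominates(
                    (sub.n_linked, sub.s), (b["n_linked"], b["s"])
                )
                for b in baselines[site]
            ),
        }
        for site, sub in subnetworks.items()
    }
    if cross is not None:
        summary["cross_site"] = {
            "per_site": cross["per_site"].to_dict(orient="records"),
            "global_intersection_size": len(cross["global_intersection"]),
        }
    summary["stages"].append("subnetwork")

    summary["manifest"] = sorted(manifest)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
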