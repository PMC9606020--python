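"""End-to-end orchestration: simulate -> signature -> score -> classify ->
balance -> differential calling -> networks -> drug response.

Stages communicate only via files (TSV/GMT) under the output directory, so
every stage is independently invokable; a JSON manifest records the config
snapshot, seed, per-stage output digests and record counts. Re-running
with an identical config and seed reproduces byte-identical outputs and
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .balance import PropensityBalancer, balance_table
from .diff import LAYER_SPECS, LayerSpec, analyze_layer
from .drugs import gene_drug_associations, score_drug_associations
from .grouping import classify_by_cancer, eligible_cancers
from .io import (
    GeneSetCollection,
    write_gmt,
    write_matrix,
    write_sample_table,
    write_table,
)
from .network import (
    build_network,
    feature_recurrence,
    max_abs_effect,
    network_tables,
    select_recurrent_regulators,
    select_recurrent_targets,
)
from .signature import (
    derive_consensus_signature,
    select_consistent_lists,
    validate_gene_lists,
)
from .simulate import (
    SimConfig,
    gen_drug_panel,
    gen_imputed_drug_response,
    gen_labeled_validation_sets,
    gen_multiomics_cohort,
    gen_regulatory_pairs,
)
from .ssgsea import SsgseaParams, score_matrix

logger = logging.getLogger("autoscore")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_genes": 2000,
        "n_samples": 600,
        "signature_size": 37,
        "signature_effect": 2.0,
        "n_datasets": 6,
        "n_lists": 6,
        "n_signal_lists": 4,
        "n_per_group": 20,
        "n_cell_lines": 200,
        "pair_density": 0.1,
        "n_tfs": 40,
    },
    "thresholds": {
        "alpha_v": 0.05,
        "min_datasets": 4,
        "min_group_n": 30,
        "balance_threshold": 0.1,
        "fdr_threshold": 0.05,
        "effect_mRNA": 2.0,
        "effect_miRNA": 1.5,
        "effect_difference": 0.2,
        "n_perm": 100,
        "perm_alpha": 0.05,
        "rs_min_cell_lines": 0.3,
        "rs_min_cohort": 0.2,
        # recurrence thresholds; the single-cancer synthetic run uses 1
        "min_cancers_tf": 1,
        "min_cancers_mirna": 1,
        "min_cancers_target": 1,
    },
}


def validate_config(config: dict) -> dict:
    """Merge onto defaults and check every threshold's domain."""
    cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    th = cfg["thresholds"]
    if not 0 < th["fdr_threshold"] <= 1:
        raise ValueError(f"fdr_threshold out of domain: {th['fdr_threshold']}")
    if not 0 < th["alpha_v"] <= 1:
        raise ValueError(f"alpha_v out of domain: {th['alpha_v']}")
    if not 0 < th["perm_alpha"] <= 1:
        raise ValueError(f"perm_alpha out of domain: {th['perm_alpha']}")
    for k in ("effect_mRNA", "effect_miRNA", "effect_difference"):
        if th[k] < 0:
            raise ValueError(f"{k} must be non-negative")
    for k in ("rs_min_cell_lines", "rs_min_cohort"):
        if not 0 <= th[k] < 1:
            raise ValueError(f"{k} out of domain: {th[k]}")
    if th["n_perm"] < 1:
        raise ValueError("n_perm must be >= 1")
    if int(cfg["seed"]) < 0:
        raise ValueError("seed must be non-negative")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
    # paths are stored relative to the run directory so identical runs into
    # different directories still produce identical manifests
    manifest["stages"][stage] = {
        "outputs": {name: {"path": p.name, "sha256": _digest(p)} for name, p in outputs.items()},
        "records": counts,
    }


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return validate_config(yaml.safe_load(fh) or {})


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute all stages on a simulated study; returns the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    th = config["thresholds"]
    sim = config["simulate"]
    manifest: dict = {"version": __version__, "seed": seed, "config": config, "stages": {}}

    sim_cfg = SimConfig(
        seed=seed,
        n_genes=int(sim["n_genes"]),
        n_samples=int(sim["n_samples"]),
        signature_size=int(sim["signature_size"]),
        signature_effect=float(sim["signature_effect"]),
        n_cell_lines=int(sim["n_cell_lines"]),
    )

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        datasets, lists, truth = gen_labeled_validation_sets(
            sim_cfg,
            n_datasets=int(sim["n_datasets"]),
            n_lists=int(sim["n_lists"]),
            n_signal_lists=int(sim["n_signal_lists"]),
            n_per_group=int(sim["n_per_group"]),
        )
        cohort = gen_multiomics_cohort(sim_cfg, signature=truth)
        panel = gen_drug_panel(sim_cfg)
        write_gmt(lists, out / "candidate_lists.gmt")
        outputs = {"candidate_lists": out / "candidate_lists.gmt"}
        counts = {"candidate_lists": len(lists)}
        for ds in datasets:
            write_matrix(ds.matrix, out / f"{ds.name}_matrix.tsv")
            ds.labels.rename("label").to_frame().to_csv(out / f"{ds.name}_labels.tsv", sep="\t")
            outputs[f"{ds.name}_matrix"] = out / f"{ds.name}_matrix.tsv"
        for layer, mat in cohort["layers"].items():
            write_matrix(mat, out / f"cohort_{layer}.tsv")
            outputs[f"cohort_{layer}"] = out / f"cohort_{layer}.tsv"
            counts[f"cohort_{layer}"] = len(mat)
        write_sample_table(cohort["samples"], out / "cohort_samples.tsv")
        outputs["cohort_samples"] = out / "cohort_samples.tsv"
        write_matrix(panel["expr"], out / "cellline_expr.tsv")
        write_matrix(panel["auc"], out / "cellline_auc.tsv")
        write_table(panel["truth"], out / "drug_truth.tsv")
        outputs["cellline_expr"] = out / "cellline_expr.tsv"
        outputs["cellline_auc"] = out / "cellline_auc.tsv"
        state.update(datasets=datasets, lists=lists, truth=truth, cohort=cohort, panel=panel)
        _record(manifest, "simulate", outputs, counts)

    @stage("derive_signature")
    def _derive():
        outcomes = validate_gene_lists(
            state["lists"], state["datasets"], alpha_v=float(th["alpha_v"])
        )
        retained = select_consistent_lists(outcomes, min_datasets=int(th["min_datasets"]))
        consensus = derive_consensus_signature(
            GeneSetCollection([state["lists"][n] for n in retained])
        )
        write_table(outcomes, out / "validation_outcomes.tsv")
        write_gmt(GeneSetCollection([consensus]), out / "signature.gmt")
        state["signature"] = consensus
        _record(
            manifest,
            "derive_signature",
            {"outcomes": out / "validation_outcomes.tsv", "signature": out / "signature.gmt"},
            {"retained_lists": len(retained), "signature_genes": len(consensus)},
        )

    @stage("score")
    def _score():
        cohort = state["cohort"]
        scores = score_matrix(cohort["layers"]["mRNA"], state["signature"], SsgseaParams()).iloc[0]
        scores.rename("score").to_frame().to_csv(out / "scores.tsv", sep="\t")
        state["scores"] = scores
        _record(manifest, "score", {"scores": out / "scores.tsv"}, {"samples": len(scores)})

    @stage("classify")
    def _classify():
        cohort = state["cohort"]
        cancer_of = cohort["samples"]["cancer_type"]
        assignments = classify_by_cancer(state["scores"], cancer_of)
        eligible = eligible_cancers(assignments, min_n=int(th["min_group_n"]))
        labels = pd.concat([a.labels for a in assignments.values()])
        frame = labels.rename("group").to_frame()
        frame["cancer_type"] = cancer_of.reindex(frame.index)
        frame.to_csv(out / "groups.tsv", sep="\t")
        state["assignments"] = {c: assignments[c] for c in eligible}
        state["eligible"] = eligible
        _record(
            manifest, "classify", {"groups": out / "groups.tsv"},
            {"eligible_cancers": len(eligible)},
        )

    @stage("balance")
    def _balance():
        cohort = state["cohort"]
        covs = [c.name for c in sim_cfg.confounders]
        weights_all, tables = [], []
        state["balance"] = {}
        for cancer in state["eligible"]:
            asg = state["assignments"][cancer]
            samp = cohort["samples"].loc[asg.labels.index]
            bal = PropensityBalancer(covariates=covs, threshold=float(th["balance_threshold"]))
            bal.fit(samp, asg.labels)
            weights_all.append(bal.weights_)
            tab = balance_table(samp.loc[bal.weights_.index], asg.labels, bal.weights_, covs)
            tab.insert(0, "cancer", cancer)
            tables.append(tab)
            state["balance"][cancer] = bal
        weights = pd.concat(weights_all)
        weights.rename("weight").to_frame().to_csv(out / "weights.tsv", sep="\t")
        write_table(pd.concat(tables, ignore_index=True), out / "balance_table.tsv")
        state["weights"] = weights
        _record(
            manifest, "balance",
            {"weights": out / "weights.tsv", "balance_table": out / "balance_table.tsv"},
            {"weighted_samples": len(weights)},
        )

    @stage("diff")
    def _diff():
        cohort = state["cohort"]
        state["diff"] = {}
        outputs, counts = {}, {}
        for cancer in state["eligible"]:
            asg = state["assignments"][cancer]
            hl = asg.labels.index[asg.labels.isin(["high", "low"])]
            hl = hl.intersection(state["weights"].index)
            state["diff"][cancer] = {}
            for layer, mat in cohort["layers"].items():
                spec = _layer_spec(layer, th)
                res = analyze_layer(
                    mat[hl], asg.labels.loc[hl], state["weights"], spec,
                    n_perm=int(th["n_perm"]), perm_alpha=float(th["perm_alpha"]), seed=seed,
                )
                path = out / f"diff_{cancer}_{layer}.tsv"
                res.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
                outputs[f"diff_{cancer}_{layer}"] = path
                counts[f"diff_{cancer}_{layer}"] = int(res["significant"].sum())
                state["diff"][cancer][layer] = res
        _record(manifest, "diff", outputs, counts)

    @stage("network")
    def _network():
        cohort = state["cohort"]
        mrna_by_cancer = {c: layers["mRNA"] for c, layers in state["diff"].items()}
        mirna_by_cancer = {c: layers["miRNA"] for c, layers in state["diff"].items()}
        genes = list(cohort["layers"]["mRNA"].index)
        mirnas = list(cohort["layers"]["miRNA"].index)
        rng_tfs = genes[: int(sim["n_tfs"])]
        targets = select_recurrent_targets(mrna_by_cancer, int(th["min_cancers_target"]))
        outputs, counts = {}, {}
        for kind, per_cancer, regs_all, min_c in (
            ("TF", mrna_by_cancer, rng_tfs, int(th["min_cancers_tf"])),
            ("miRNA", mirna_by_cancer, mirnas, int(th["min_cancers_mirna"])),
        ):
            regulators = select_recurrent_regulators(
                per_cancer, kind, min_cancers=min_c, members=regs_all
            )
            pairs = gen_regulatory_pairs(sim_cfg, regs_all, genes, float(sim["pair_density"]))
            rec = pd.concat([feature_recurrence(per_cancer), feature_recurrence(mrna_by_cancer)])
            rec = rec[~rec.index.duplicated()]
            eff = pd.concat([max_abs_effect(per_cancer), max_abs_effect(mrna_by_cancer)])
            eff = eff[~eff.index.duplicated()]
            net = build_network(regulators, targets, pairs, rec, eff, kind=kind)
            edges, nodes = network_tables(net)
            write_table(edges, out / f"network_{kind}_edges.tsv")
            write_table(nodes, out / f"network_{kind}_nodes.tsv")
            outputs[f"network_{kind}_edges"] = out / f"network_{kind}_edges.tsv"
            outputs[f"network_{kind}_nodes"] = out / f"network_{kind}_nodes.tsv"
            counts[f"{kind}_regulators"] = len(regulators)
            counts[f"{kind}_edges"] = len(edges)
        _record(manifest, "network", outputs, counts)

    @stage("drugs")
    def _drugs():
        panel = state["panel"]
        assoc = gene_drug_associations(
            panel["expr"], panel["auc"],
            rs_min=float(th["rs_min_cell_lines"]), fdr_max=float(th["fdr_threshold"]),
        )
        write_table(assoc, out / "drug_assoc_cell_lines.tsv")
        imputed = gen_imputed_drug_response(sim_cfg, state["scores"])
        cohort_scores = {c: state["scores"][state["assignments"][c].labels.index]
                         for c in state["eligible"]}
        assoc2 = score_drug_associations(
            cohort_scores, imputed["imputed"],
            rs_min=float(th["rs_min_cohort"]), fdr_max=float(th["fdr_threshold"]),
        )
        write_table(assoc2, out / "drug_assoc_cohort.tsv")
        _record(
            manifest, "drugs",
            {"cell_lines": out / "drug_assoc_cell_lines.tsv",
             "cohort": out / "drug_assoc_cohort.tsv"},
            {"cell_line_pairs": len(assoc), "cohort_pairs": len(assoc2),
             "labeled_cell_line": int((assoc["label"] != "none").sum()) if len(assoc) else 0},
        )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _layer_spec(layer: str, th: dict) -> LayerSpec:
    spec = LAYER_SPECS[layer]
    overrides = {
        "mRNA": th.get("effect_mRNA"),
        "miRNA": th.get("effect_miRNA"),
        "protein": th.get("effect_difference"),
        "methylation": th.get("effect_difference"),
    }
    eff = overrides.get(layer)
    from dataclasses import replace

    if eff is not None:
        spec = replace(spec, effect_threshold=float(eff))
    return replace(spec, fdr_threshold=float(th["fdr_threshold"]))
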