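"""End-to-end orchestration: resting interactome and perturbation remodeling.

Two entry points mirror the two study designs:

* :func:`run_resting` — several baits, one negative control: parse/filter/
  impute, per-bait co-enrichment + correlation calling, network assembly and
  overlap summary.
* :func:`run_perturbation` — one bait under a control background and several
  genetic perturbations: per-condition calling (with per-condition threshold
  overrides), then gained/shared/lost remodeling, a clustered log2FC matrix
  and a sample PCA.

Both are fully reproducible from a single master seed; per-comparison seeds
are derived from it.  Configuration is a plain dict (typically loaded from
YAML); defaults mirror the standard analysis parameters (s0=1, permutation
FDR 0.05/0.10 for Classes A/B, imputation shift 1.8 / width 0.3, local
correlation threshold 0.6, global correlation FDR 0.05, replicate-presence
quota 2).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation as corr_mod
from . import enrichment as enr_mod
from . import interactome as net_mod
from . import quant
from . import remodeling as rem_mod
from .quant import AnnotationSet, QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "prepare_matrix", "call_interactors", "run_resting", "run_perturbation", "load_config"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of one comparison; defaults are the standard values."""

    s0: float = 1.0
    fdr_a: float = 0.05
    fdr_b: float = 0.10
    local_r: float = 0.6
    fdr_global: float = 0.05
    n_permutations: int = 250
    min_reps: int = 2
    replicate_scope: str = "per-condition"
    impute_shift: float = 1.8
    impute_width: float = 0.3

    def override(self, **kw) -> "PipelineParams":
        kw = {k: v for k, v in kw.items() if v is not None}
        unknown = set(kw) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        return dataclasses.replace(self, **kw)


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def prepare_matrix(
    m: QuantMatrix,
    design: SampleDesign,
    ann: AnnotationSet | None,
    params: PipelineParams,
    seed: int,
    conditions=None,
    report: dict | None = None,
) -> QuantMatrix:
    """Standard preprocessing: flag filter, mito filter, log2, replicate filter, impute."""

    def log_stage(name: str, mat: QuantMatrix) -> None:
        if report is not None:
            report.setdefault("stages", {})[name] = {"n_proteins": mat.n_proteins}

    log_stage("input", m)
    m = quant.filter_flagged(m)
    log_stage("filter_flagged", m)
    if ann is not None:
        m = quant.annotate_mitochondrial(m, ann, drop=True)
        log_stage("mito_filter", m)
    m = quant.log2_transform(m)
    m = quant.replicate_presence_filter(
        m, design, min_reps=params.min_reps, scope=params.replicate_scope, conditions=conditions
    )
    log_stage("replicate_filter", m)
    m = quant.impute_missing_downshifted(
        m, shift=params.impute_shift, width=params.impute_width, seed=seed
    )
    if report is not None:
        report.setdefault("seeds", {})["imputation"] = seed
    return m


def call_interactors(
    m_imp: QuantMatrix,
    design: SampleDesign,
    bait_condition: str,
    control_condition: str,
    params: PipelineParams,
    seed: int,
) -> dict:
    """One bait-versus-control comparison: enrichment, correlation, merged calls."""
    spec = enr_mod.ComparisonSpec(
        bait_condition=bait_condition,
        control_condition=control_condition,
        s0=params.s0,
        fdr_class_a=params.fdr_a,
        fdr_class_b=params.fdr_b,
        n_permutations=params.n_permutations,
        seed=seed,
    )
    enr = enr_mod.enrich(m_imp, design, spec)
    class_a_preys = enr.index[enr["fdr_class"] == "A"]
    corr_table, cfg = corr_mod.correlate(
        m_imp,
        design,
        bait_condition,
        control_condition,
        cfg=corr_mod.LocalThresholdConfig(threshold=params.local_r),
        class_a_preys=class_a_preys,
        fdr_global=params.fdr_global,
        n_permutations=params.n_permutations,
        seed=seed + 1,
    )
    bait_name = design.bait_name_of(bait_condition)
    calls = net_mod.assign_interactor_classes(enr, corr_table, bait=bait_name)
    return {
        "bait_condition": bait_condition,
        "bait_name": bait_name,
        "enrichment": enr,
        "correlation": corr_table,
        "calls": calls,
        "local_threshold": cfg,
        "seed": seed,
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _resolve_inputs(config: dict):
    design = SampleDesign.from_tsv(config["design"])
    m = quant.parse_protein_groups(config["protein_groups"], design)
    ann = AnnotationSet.from_file(config["mito_list"]) if config.get("mito_list") else None
    return m, design, ann


def _check_conditions(design: SampleDesign, comparisons: list[dict]) -> None:
    known = set(design.conditions)
    for comp in comparisons:
        for key in ("bait_condition", "control_condition"):
            if comp[key] not in known:
                raise ValueError(f"unknown condition {comp[key]!r} in config (known: {sorted(known)})")


def _write_comparison(outdir: Path, tag: str, result: dict) -> None:
    result["enrichment"].to_csv(outdir / f"{tag}_enrichment.tsv", sep="\t")
    result["correlation"].to_csv(outdir / f"{tag}_correlation.tsv", sep="\t")
    result["calls"].to_csv(outdir / f"{tag}_calls.tsv", sep="\t", index=False)
    enr_mod.volcano_table(result["enrichment"]).to_csv(outdir / f"{tag}_volcano.tsv", sep="\t")


def run_resting(
    config: dict | str | Path,
    m: QuantMatrix | None = None,
    design: SampleDesign | None = None,
    ann: AnnotationSet | None = None,
) -> dict:
    """Resting-interactome run: per-bait calling, network, overlap summary.

    ``config`` is a dict (or YAML path) with keys ``comparisons`` (list of
    {bait_condition, control_condition, overrides?}), optional ``params``,
    ``seed`` and ``outdir``; input objects may be passed directly or named by
    ``protein_groups``/``design``/``mito_list`` paths.  Returns the run
    report with comparison results attached under ``"results"``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if m is None or design is None:
        m, design, ann_loaded = _resolve_inputs(config)
        ann = ann if ann is not None else ann_loaded
    base_params = PipelineParams().override(**config.get("params", {}))
    comparisons = config["comparisons"]
    _check_conditions(design, comparisons)
    master_seed = int(config.get("seed", 0))
    seeds = _derive_seeds(master_seed, 2 * len(comparisons) + 1)

    report: dict = {"mode": "resting", "master_seed": master_seed, "comparisons": {}, "warnings": []}
    m_imp = prepare_matrix(m, design, ann, base_params, seed=seeds[0], report=report)

    results = {}
    calls_by_bait = {}
    prey_sets = {}
    for k, comp in enumerate(comparisons):
        params = base_params.override(**comp.get("overrides", {}))
        res = call_interactors(
            m_imp, design, comp["bait_condition"], comp["control_condition"], params, seed=seeds[1 + 2 * k]
        )
        tag = comp["bait_condition"]
        results[tag] = res
        # a perturbation series re-uses one bait across conditions; fall back
        # to the condition tag to keep per-comparison entries distinct
        key = res["bait_name"] if res["bait_name"] not in calls_by_bait else tag
        calls_by_bait[key] = res["calls"]
        prey_sets[key] = set(res["calls"].loc[~res["calls"]["self_flag"], "prey"])
        enr = res["enrichment"]
        report["comparisons"][tag] = {
            "bait": res["bait_name"],
            "seed": res["seed"],
            "params": dataclasses.asdict(params),
            "threshold_d_A": enr.attrs["threshold_d_A"],
            "threshold_d_B": enr.attrs["threshold_d_B"],
            "n_assignments": enr.attrs["n_assignments"],
            "enumerated": enr.attrs["enumerated"],
            "derived_class_a_mean_r": res["local_threshold"].derived_class_a_mean,
            "n_interactors": int(len(res["calls"])),
            "class_counts": {
                c: int(res["calls"]["classes"].str.contains(c).sum()) for c in net_mod.CLASS_ORDER
            },
        }

    edge_table, node_table = net_mod.build_network(calls_by_bait)
    report["network"] = {
        "n_edges": int(len(edge_table)),
        "n_nodes": int(len(node_table)),
        "n_known_subunits_recovered": int(node_table["is_known_subunit"].sum()),
    }
    if len(prey_sets) >= 2:
        report["overlap"] = net_mod.overlap_summary(prey_sets)

    outdir = config.get("outdir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        quant.write_matrix_tsv(m_imp, outdir / "matrix_imputed.tsv", outdir / "matrix_mask.tsv")
        for tag, res in results.items():
            _write_comparison(outdir, tag, res)
        edge_table.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        node_table.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        net_mod.write_sif(edge_table, outdir / "network.sif")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    report["results"] = results
    report["edges"] = edge_table
    report["nodes"] = node_table
    return report


def run_perturbation(
    config: dict | str | Path,
    m: QuantMatrix | None = None,
    design: SampleDesign | None = None,
    ann: AnnotationSet | None = None,
) -> dict:
    """Perturbation-remodeling run.

    Config adds ``control_comparison`` (the condition whose interactome is
    the remodeling baseline, e.g. the empty-vector line) and optionally
    ``remodel_classes`` (evidence classes defining an interactor for the
    comparison; default "ABC") and ``heatmap_missing`` policy.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if m is None or design is None:
        m, design, ann_loaded = _resolve_inputs(config)
        ann = ann if ann is not None else ann_loaded
    baseline_cond = config["control_comparison"]
    comparisons = config["comparisons"]
    _check_conditions(design, comparisons)
    if baseline_cond not in [c["bait_condition"] for c in comparisons]:
        raise ValueError(f"control_comparison {baseline_cond!r} is not among the comparisons")
    remodel_classes = tuple(config.get("remodel_classes", "ABC"))

    report = run_resting({**config, "outdir": None}, m=m, design=design, ann=ann)
    report["mode"] = "perturbation"
    results = report["results"]

    def interactor_set(tag: str) -> set:
        calls = results[tag]["calls"]
        mask = calls["classes"].apply(lambda c: any(k in c for k in remodel_classes))
        return set(calls.loc[mask & ~calls["self_flag"], "prey"])

    control_set = interactor_set(baseline_cond)
    condition_sets = {
        c["bait_condition"]: interactor_set(c["bait_condition"])
        for c in comparisons
        if c["bait_condition"] != baseline_cond
    }
    summary = rem_mod.remodeling_summary(control_set, condition_sets)
    report["remodeling"] = {
        cond: {k: row[k] for k in ("gained_pct", "shared_pct", "lost_pct", "union_size")}
        for cond, row in summary.iterrows()
    }

    universe = sorted(control_set.union(*condition_sets.values()) if condition_sets else control_set)
    enr_by_cond = {tag: res["enrichment"] for tag, res in results.items()}
    fc = rem_mod.log2fc_matrix(enr_by_cond, universe) if len(universe) >= 1 else None
    clustered = None
    if fc is not None and fc.shape[0] >= 2:
        clustered = rem_mod.hclust_complete_euclidean(fc, missing=config.get("heatmap_missing", "zero-fill"))
        report["heatmap_leaf_order"] = list(clustered.leaf_order)

    # PCA on the imputed matrix used for calling
    base_params = PipelineParams().override(**config.get("params", {}))
    seeds = _derive_seeds(int(config.get("seed", 0)), 1)
    m_imp = prepare_matrix(m, design, ann, base_params, seed=seeds[0])
    pca = rem_mod.pca_samples(m_imp, design)
    report["pca_explained_variance_ratio"] = pca["explained_variance_ratio"]

    outdir = config.get("outdir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tag, res in results.items():
            _write_comparison(outdir, tag, res)
        summary_out = summary[["gained_pct", "shared_pct", "lost_pct", "union_size"]]
        summary_out.to_csv(outdir / "remodeling_summary.tsv", sep="\t")
        (outdir / "remodeling_summary.json").write_text(
            json.dumps(report["remodeling"], indent=2, sort_keys=True)
        )
        if clustered is not None:
            clustered.data.to_csv(outdir / "log2fc_clustered.tsv", sep="\t")
        pca["coordinates"].to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        persisted = {k: v for k, v in report.items() if k not in ("results", "edges", "nodes")}
        (outdir / "report.json").write_text(json.dumps(persisted, indent=2, sort_keys=True, default=str))
    report["remodeling_table"] = summary
    report["log2fc_matrix"] = fc
    report["clustered"] = clustered
    report["pca"] = pca
    return report
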