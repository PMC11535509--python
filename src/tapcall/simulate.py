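"""Synthetic TAP-MS datasets with planted ground truth.

The generator emulates the statistical structure the calling pipeline
assumes: log-normal protein abundances (normal on the log2 scale),
additive log2 enrichment of planted interactors in their bait's TAP
samples, correlation between planted-prey and bait profiles through a
shared latent per-sample bait-abundance factor, and intensity-dependent
(left-censored, missing-not-at-random) dropout via a logistic censoring
curve.  Everything derives from a single master seed through named
per-stage streams, so datasets are bit-reproducible.

It does not emulate peptide-level effects, shared-peptide protein
inference, ratio compression, or batch structure; see the methods note for
what that implies about test coverage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .interactome import overlap_summary
from .remodeling import compare_to_control
from .quant import (
    RAW_LINEAR,
    AnnotationSet,
    ProteinRecord,
    QuantMatrix,
    SampleDesign,
    write_protein_groups,
)

__all__ = [
    "BaitSpec",
    "SimConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "evaluate_recovery",
    "make_reference_fixtures",
]


@dataclass(frozen=True)
class BaitSpec:
    """One bait condition: its name, replicate count and tagged protein.

    ``bait_protein`` defaults to the condition name; setting it explicitly
    lets several conditions share one bait (perturbation series of the same
    tagged line).
    """

    name: str
    n_replicates: int = 4
    bait_protein: str | None = None

    @property
    def protein(self) -> str:
        return self.bait_protein or self.name


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (log2 units unless noted).

    Defaults follow a typical deep TAP-MS experiment: four biological
    replicates per TAP, log2 LFQ intensities centred near 25 with a spread
    of 2, replicate noise SD 0.5, a ~20-fold enriched bait, and logistic
    left-censoring with midpoint 4 SD below the intensity centre.
    """

    n_proteins: int = 1000
    fraction_mito: float = 0.85
    baits: tuple[BaitSpec, ...] = (BaitSpec("MCU", 4),)
    n_control_replicates: int = 4
    control_name: str = "Ctrl-TAP"
    planted: dict = field(default_factory=dict)  # condition -> [(prey_index, log2 effect)]
    base_intensity_mean: float = 25.0
    base_intensity_sd: float = 2.0
    replicate_noise_sd: float = 0.5
    bait_coupling: float = 0.7
    bait_latent_sd: float = 0.5
    bait_log2_enrichment: float = math.log2(20.0)
    missing_midpoint: float | None = 21.0  # None disables censoring
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not (0 <= self.fraction_mito <= 1):
            raise ValueError("fraction_mito must lie in [0, 1]")
        if not (0 <= self.bait_coupling <= 1):
            raise ValueError("bait_coupling must lie in [0, 1]")
        if not self.baits:
            raise ValueError("at least one bait condition required")
        for b in self.baits:
            if b.n_replicates < 2:
                raise ValueError(f"bait {b.name!r} needs >= 2 replicates")
        if self.n_control_replicates < 2:
            raise ValueError("need >= 2 control replicates")
        names = [b.name for b in self.baits]
        if len(set(names)) != len(names):
            raise ValueError("bait condition names must be unique")
        for cond, pairs in self.planted.items():
            if cond not in names:
                raise ValueError(f"planted condition {cond!r} is not a bait condition")
            for idx, eff in pairs:
                if not (0 <= idx < self.n_proteins):
                    raise ValueError(f"planted prey index {idx} out of range")
                if not math.isfinite(eff):
                    raise ValueError("planted effect sizes must be finite")
        if self.missing_midpoint is not None and self.missing_slope <= 0:
            raise ValueError("missing_slope must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted interactors (with effect sizes) per condition, plus mito labels."""

    planted: dict  # condition -> {prey_id: effect}
    mito_ids: frozenset[str]
    bait_rows: dict  # bait protein name -> row index

    def planted_set(self, condition: str) -> set[str]:
        return set(self.planted.get(condition, {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": cond, "prey": prey, "effect": eff}
            for cond, d in self.planted.items()
            for prey, eff in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["condition", "prey", "effect"])


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[QuantMatrix, SampleDesign, AnnotationSet, SyntheticTruth]:
    """Draw one dataset; returns (raw-linear matrix, design, mito list, truth).

    Bait proteins occupy the leading rows (one per distinct tagged protein)
    with their baseline pinned to the intensity centre, are enriched by
    ``bait_log2_enrichment`` in their own TAP samples, and fluctuate there
    with a per-sample latent abundance factor; planted preys receive their
    log2 effect plus ``bait_coupling`` times the same latent factor, which is
    what makes prey profiles correlate with the bait's.
    """
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("baseline", "noise", "latent", "mito", "censor"),
            np.random.SeedSequence(cfg.seed).spawn(5),
        )
    }
    bait_proteins = list(dict.fromkeys(b.protein for b in cfg.baits))
    bait_rows = {name: i for i, name in enumerate(bait_proteins)}

    # sample layout: control first, then each bait condition
    design_rows = []
    for r in range(cfg.n_control_replicates):
        design_rows.append(
            {
                "sample_id": f"{cfg.control_name}_r{r+1}",
                "condition": cfg.control_name,
                "replicate": r + 1,
                "role": "control",
                "bait_name": None,
            }
        )
    for b in cfg.baits:
        for r in range(b.n_replicates):
            design_rows.append(
                {
                    "sample_id": f"{b.name}_r{r+1}",
                    "condition": b.name,
                    "replicate": r + 1,
                    "role": "bait",
                    "bait_name": b.protein,
                }
            )
    design = SampleDesign(pd.DataFrame(design_rows))
    sample_ids = design.sample_ids
    n_samp = len(sample_ids)
    col_of = {s: j for j, s in enumerate(sample_ids)}

    baseline = streams["baseline"].normal(cfg.base_intensity_mean, cfg.base_intensity_sd, cfg.n_proteins)
    baseline[list(bait_rows.values())] = cfg.base_intensity_mean
    log2_values = baseline[:, None] + streams["noise"].normal(
        0.0, cfg.replicate_noise_sd, (cfg.n_proteins, n_samp)
    )

    truth_planted: dict[str, dict[str, float]] = {}
    for b in cfg.baits:
        cols = [col_of[s] for s in design.samples_of(b.name)]
        latent = streams["latent"].normal(0.0, cfg.bait_latent_sd, len(cols))
        brow = bait_rows[b.protein]
        log2_values[brow, cols] += cfg.bait_log2_enrichment + latent
        planted_here: dict[str, float] = {}
        for idx, eff in cfg.planted.get(b.name, []):
            log2_values[idx, cols] += eff + cfg.bait_coupling * latent
            planted_here[_protein_id(idx) if idx not in bait_rows.values() else bait_proteins[idx]] = float(eff)
        truth_planted[b.name] = planted_here

    # mitochondrial labels: baits and planted preys always mito, rest random
    is_mito = streams["mito"].random(cfg.n_proteins) < cfg.fraction_mito
    is_mito[list(bait_rows.values())] = True
    for b in cfg.baits:
        for idx, _ in cfg.planted.get(b.name, []):
            is_mito[idx] = True

    # left-censored missingness
    if cfg.missing_midpoint is not None:
        p_miss = expit((cfg.missing_midpoint - log2_values) / cfg.missing_slope)
        missing = streams["censor"].random(log2_values.shape) < p_miss
        # keep every column imputable
        for j in range(n_samp):
            if (~missing[:, j]).sum() < 2:
                missing[:2, j] = False
    else:
        missing = np.zeros(log2_values.shape, dtype=bool)

    proteins = []
    for i in range(cfg.n_proteins):
        if i in bait_rows.values():
            name = bait_proteins[i]
            proteins.append(
                ProteinRecord(group_id=name, all_ids=(name,), gene_symbol=name, is_mito=bool(is_mito[i]))
            )
        else:
            pid = _protein_id(i)
            proteins.append(
                ProteinRecord(group_id=pid, all_ids=(pid,), gene_symbol=f"G{i:04d}", is_mito=bool(is_mito[i]))
            )

    linear = np.exp2(log2_values)
    values = np.where(missing, np.nan, linear)
    m = QuantMatrix(
        proteins=proteins,
        samples=sample_ids,
        values=values,
        observed=~missing,
        ibaq=linear.copy(),  # iBAQ proxy: abundances already on the per-peptide-normalized scale
        scale_tag=RAW_LINEAR,
    )
    ann = AnnotationSet(
        ids=frozenset(p.group_id for p, flag in zip(proteins, is_mito) if flag),
        name="synthetic-mito",
    )
    truth = SyntheticTruth(
        planted=truth_planted,
        mito_ids=ann.ids,
        bait_rows=dict(bait_rows),
    )
    return m, design, ann, truth


# ---------------------------------------------------------------------------
# Recovery scoring


def evaluate_recovery(
    truth: SyntheticTruth,
    calls_by_condition: dict[str, pd.DataFrame],
    classes: tuple[str, ...] = ("A",),
) -> dict:
    """Precision/recall/false-discovery proportion of calls against planted truth.

    A call counts when its evidence classes intersect ``classes``; bait
    self-rows are excluded from both sides.  ``precision`` and ``fdp`` are
    None (undefined sentinel) when nothing is called; the micro average pools
    counts over conditions.
    """
    per_condition = {}
    tp_tot = called_tot = truth_tot = 0
    any_content = False
    for cond, calls in calls_by_condition.items():
        truth_set = truth.planted_set(cond) - set(truth.bait_rows)
        mask = calls["classes"].apply(lambda c: any(k in c for k in classes)) & ~calls["self_flag"]
        called = set(calls.loc[mask, "prey"]) - set(truth.bait_rows)
        if truth_set or called:
            any_content = True
        tp = len(called & truth_set)
        per_condition[cond] = {
            "n_truth": len(truth_set),
            "n_called": len(called),
            "tp": tp,
            "precision": tp / len(called) if called else None,
            "recall": tp / len(truth_set) if truth_set else None,
            "fdp": (len(called) - tp) / len(called) if called else None,
        }
        tp_tot += tp
        called_tot += len(called)
        truth_tot += len(truth_set)
    if not any_content:
        return {"per_condition": per_condition, "micro": None}
    micro = {
        "tp": tp_tot,
        "n_called": called_tot,
        "n_truth": truth_tot,
        "precision": tp_tot / called_tot if called_tot else None,
        "recall": tp_tot / truth_tot if truth_tot else None,
        "fdp": (called_tot - tp_tot) / called_tot if called_tot else None,
    }
    return {"per_condition": per_condition, "micro": micro}


# ---------------------------------------------------------------------------
# Reference fixtures


EXHAUSTIVE_FIXTURE = {
    # 3 proteins, 2 bait + 2 control samples: small enough that all C(4,2)=6
    # label assignments of the permutation null can be enumerated by hand.
    "samples_bait": ["bait_r1", "bait_r2"],
    "samples_ctrl": ["ctrl_r1", "ctrl_r2"],
    "log2_values": {
        "PREY1": [14.0, 14.5, 10.0, 10.5],  # strongly enriched
        "PREY2": [11.0, 11.4, 10.8, 11.2],  # marginal
        "PREY3": [10.0, 10.6, 10.2, 10.4],  # flat
    },
}


def _sim_config_overlap(seed: int) -> SimConfig:
    """Three baits sharing planted preys in a known overlap structure."""
    planted = {
        # indices 3.. are ordinary proteins (0-2 are the three bait rows)
        "MCU": [(10, 5.0), (11, 5.0), (12, 5.0), (13, 5.0), (20, 5.0)],
        "EMRE": [(10, 5.0), (11, 5.0), (12, 5.0), (14, 5.0), (21, 5.0)],
        "MCUB": [(10, 5.0), (11, 5.0), (15, 5.0), (22, 5.0)],
    }
    return SimConfig(
        n_proteins=400,
        baits=(BaitSpec("MCU", 4), BaitSpec("EMRE", 4), BaitSpec("MCUB", 4)),
        planted=planted,
        missing_midpoint=None,
        seed=seed,
    )


def _sim_config_remodeling(seed: int) -> SimConfig:
    """MCU bait under control and two perturbations: one loses, one gains preys."""
    base = [(10, 5.0), (11, 5.0), (12, 5.0), (13, 5.0)]
    planted = {
        "pLKO": base,
        "sh-LOSS": base[:2],                      # strict subset: lost only
        "sh-GAIN": base + [(20, 5.0), (21, 5.0)],  # superset: gained only
    }
    return SimConfig(
        n_proteins=300,
        baits=(
            BaitSpec("pLKO", 4, bait_protein="MCU"),
            BaitSpec("sh-LOSS", 4, bait_protein="MCU"),
            BaitSpec("sh-GAIN", 4, bait_protein="MCU"),
        ),
        planted=planted,
        missing_midpoint=None,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_reference_fixtures(out_dir: str | Path, seed: int = 7) -> dict:
    """Write the canonical small fixtures plus a manifest of expected outputs.

    Three cases: an exhaustively enumerable 2v2 permutation instance, a
    three-bait overlap dataset, and a perturbation-remodeling dataset where
    one condition strictly loses and one strictly gains planted interactors.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "cases": {}}

    # -- exhaustive case (hand-printed values) ------------------------------
    ex = EXHAUSTIVE_FIXTURE
    samples = ex["samples_bait"] + ex["samples_ctrl"]
    rows = []
    for pid, vals in ex["log2_values"].items():
        row = {"Majority protein IDs": pid, "Gene names": pid}
        for s, v in zip(samples, vals):
            row[f"LFQ intensity {s}"] = f"{2.0**v:.6g}"
        rows.append(row)
    ex_pg = out / "exhaustive_proteinGroups.tsv"
    pd.DataFrame(rows).to_csv(ex_pg, sep="\t", index=False)
    ex_design = out / "exhaustive_design.tsv"
    pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["bait-TAP"] * 2 + ["Ctrl-TAP"] * 2,
            "replicate": [1, 2, 1, 2],
            "role": ["bait", "bait", "control", "control"],
            "bait_name": ["PREY1", "PREY1", None, None],
        }
    ).to_csv(ex_design, sep="\t", index=False)
    manifest["cases"]["exhaustive"] = {
        "protein_groups": ex_pg.name,
        "design": ex_design.name,
        "n_assignments": 6,
        "n_proteins": 3,
    }

    # -- overlap case -------------------------------------------------------
    cfg_o = _sim_config_overlap(seed)
    m, design, ann, truth = simulate_dataset(cfg_o)
    write_protein_groups(m, out / "overlap_proteinGroups.tsv")
    design.to_tsv(out / "overlap_design.tsv")
    (out / "overlap_mito.txt").write_text("\n".join(sorted(ann.ids)) + "\n")
    truth.to_frame().to_csv(out / "overlap_truth.tsv", sep="\t", index=False)
    sets = {c: truth.planted_set(c) for c in truth.planted}
    manifest["cases"]["overlap"] = {
        "protein_groups": "overlap_proteinGroups.tsv",
        "design": "overlap_design.tsv",
        "truth": "overlap_truth.tsv",
        "expected_overlap": overlap_summary(sets),
    }

    # -- remodeling case ----------------------------------------------------
    cfg_r = _sim_config_remodeling(seed + 1)
    m, design, ann, truth = simulate_dataset(cfg_r)
    write_protein_groups(m, out / "remodeling_proteinGroups.tsv")
    design.to_tsv(out / "remodeling_design.tsv")
    truth.to_frame().to_csv(out / "remodeling_truth.tsv", sep="\t", index=False)
    control = truth.planted_set("pLKO")
    manifest["cases"]["remodeling"] = {
        "protein_groups": "remodeling_proteinGroups.tsv",
        "design": "remodeling_design.tsv",
        "truth": "remodeling_truth.tsv",
        "expected": {
            cond: {
                k: v
                for k, v in compare_to_control(control, truth.planted_set(cond)).items()
                if k.endswith("_pct") or k == "union_size"
            }
            for cond in ("sh-LOSS", "sh-GAIN")
        },
    }

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest["checksums"] = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
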