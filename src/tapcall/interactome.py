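"""Merging Class A-D calls into interactor verdicts and a bait-prey network.

A prey is an interactor of a bait if it belongs to at least one of the four
evidence classes: co-enrichment at the high- (A) or medium- (B) confidence
permutation FDR, local profile correlation above threshold (C), or global
profile correlation at permutation FDR (D).  Classes are computed
independently and unioned; the primary class follows the fixed order
A > B > C > D.  Edges backed by co-enrichment (A/B) are styled "co-enrichment"
(solid in the conventional network drawing), correlation-only edges (C/D)
"correlation" (dashed).

Also houses the iBAQ utilities (absolute-quantification proxy: summed peptide
intensity divided by the count of theoretically observable tryptic peptides)
and the bait-enrichment QC (bait iBAQ over the median iBAQ of all detected
proteins, per sample).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .quant import QuantMatrix, SampleDesign

__all__ = [
    "KNOWN_SUBUNITS",
    "CLASS_ORDER",
    "assign_interactor_classes",
    "build_network",
    "to_networkx",
    "write_sif",
    "overlap_summary",
    "ibaq",
    "theoretical_peptide_count",
    "bait_enrichment_qc",
]

# Known subunits of the mitochondrial calcium uniporter complex, used only
# for reporting/annotation of recovered nodes (EMRE is also known as SMDT1).
KNOWN_SUBUNITS = frozenset({"MCU", "MCUB", "EMRE", "SMDT1", "MICU1", "MICU2", "MICU3"})

CLASS_ORDER = ("A", "B", "C", "D")


def assign_interactor_classes(
    enr: pd.DataFrame, corr: pd.DataFrame, bait: str
) -> pd.DataFrame:
    """Union the four evidence classes into per-prey interactor calls.

    ``enr`` is an enrichment result table (``fdr_class`` in {A, B, none});
    ``corr`` a correlation table (``class_c``/``class_d`` booleans) over the
    same protein universe.  Only preys in at least one class are emitted.
    """
    if not enr.index.equals(corr.index):
        raise ValueError("enrichment and correlation tables cover different protein universes")
    members = {
        "A": enr["fdr_class"] == "A",
        "B": enr["fdr_class"].isin(["A", "B"]),
        "C": corr["class_c"].astype(bool),
        "D": corr["class_d"].astype(bool),
    }
    any_class = members["B"] | members["C"] | members["D"]
    rows = []
    for prey in enr.index[any_class]:
        classes = "".join(c for c in CLASS_ORDER if bool(members[c].loc[prey]))
        rows.append(
            {
                "bait": bait,
                "prey": prey,
                "classes": classes,
                "primary_class": classes[0],
                "log2fc": enr.at[prey, "log2fc"],
                "d_stat": enr.at[prey, "d_stat"],
                "perm_p": enr.at[prey, "perm_p"],
                "r_local": corr.at[prey, "r_local"],
                "r_global": corr.at[prey, "r_global"],
                "self_flag": bool(corr.at[prey, "self_flag"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bait",
            "prey",
            "classes",
            "primary_class",
            "log2fc",
            "d_stat",
            "perm_p",
            "r_local",
            "r_global",
            "self_flag",
        ],
    )


def build_network(calls_by_bait: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble deduplicated edge and node tables from per-bait calls.

    Edges are unique per (bait, prey); the ``style`` attribute records the
    evidence type ("co-enrichment" for primary class A/B, "correlation" for
    C/D).  Self edges (bait pulling down itself) are kept but flagged.
    """
    edges = []
    for bait, calls in calls_by_bait.items():
        seen = set()
        for _, row in calls.iterrows():
            key = (bait, row["prey"])
            if key in seen:
                continue
            seen.add(key)
            edges.append(
                {
                    "bait": bait,
                    "prey": row["prey"],
                    "primary_class": row["primary_class"],
                    "style": "co-enrichment" if row["primary_class"] in ("A", "B") else "correlation",
                    "log2fc": row["log2fc"],
                    "perm_p": row["perm_p"],
                    "self_flag": bool(row.get("self_flag", False)),
                }
            )
    edge_table = pd.DataFrame(
        edges,
        columns=["bait", "prey", "primary_class", "style", "log2fc", "perm_p", "self_flag"],
    )
    baits = set(calls_by_bait)
    node_ids = sorted(baits | set(edge_table["prey"]))
    node_table = pd.DataFrame(
        {
            "protein": node_ids,
            "is_bait": [n in baits for n in node_ids],
            "is_known_subunit": [n in KNOWN_SUBUNITS for n in node_ids],
        }
    )
    return edge_table, node_table


def to_networkx(edge_table: pd.DataFrame, node_table: pd.DataFrame) -> nx.Graph:
    """Materialize the edge/node tables as a networkx graph for downstream use."""
    g = nx.Graph()
    for _, row in node_table.iterrows():
        g.add_node(row["protein"], is_bait=bool(row["is_bait"]), is_known_subunit=bool(row["is_known_subunit"]))
    for _, row in edge_table.iterrows():
        g.add_edge(row["bait"], row["prey"], primary_class=row["primary_class"], style=row["style"])
    return g


def write_sif(edge_table: pd.DataFrame, path: str | Path) -> None:
    """SIF export (``bait <tab> class <tab> prey``) for graph viewers."""
    with open(path, "w") as fh:
        for _, row in edge_table.iterrows():
            fh.write(f"{row['bait']}\t{row['primary_class']}\t{row['prey']}\n")


def overlap_summary(prey_sets: dict[str, set]) -> dict:
    """Sharing structure of per-bait interactor sets.

    Counts the union, per-bait sizes, preys shared by >= 2 baits, preys common
    to all baits, and bait-specific preys (with their fraction of the union).
    """
    if len(prey_sets) < 2:
        raise ValueError("overlap summary needs >= 2 baits")
    union = set().union(*prey_sets.values())
    counts = {p: sum(p in s for s in prey_sets.values()) for p in union}
    shared_ge2 = sum(c >= 2 for c in counts.values())
    shared_all = sum(c == len(prey_sets) for c in counts.values())
    specific = sum(c == 1 for c in counts.values())
    return {
        "union_size": len(union),
        "per_bait": {b: len(s) for b, s in prey_sets.items()},
        "shared_ge2": shared_ge2,
        "shared_all": shared_all,
        "specific": specific,
        "specific_fraction": specific / len(union) if union else float("nan"),
    }


def ibaq(sum_peptide_intensity: float, n_theoretical_peptides: int) -> float:
    """Summed peptide intensity divided by the theoretically observable peptide count."""
    if sum_peptide_intensity < 0:
        raise ValueError("intensity must be non-negative")
    if n_theoretical_peptides < 1:
        raise ValueError("theoretical peptide count must be >= 1")
    return sum_peptide_intensity / n_theoretical_peptides


def theoretical_peptide_count(sequence: str, min_len: int = 7, max_len: int = 30) -> int:
    """Count fully tryptic peptides of a protein sequence.

    Cleaves after K or R except before P, zero missed cleavages; peptides
    with length in [min_len, max_len] count as observable.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("sequence contains non-amino-acid letters")
    peptides = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 >= len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return sum(min_len <= len(p) <= max_len for p in peptides)


def bait_enrichment_qc(m: QuantMatrix, design: SampleDesign, bait_condition: str) -> dict:
    """Bait iBAQ over the median iBAQ of all detected proteins, per sample.

    Summarized per condition as mean +/- SEM of the per-sample ratios; a QC
    flag is raised when the bait-condition mean ratio does not exceed the
    control-condition mean.
    """
    if m.ibaq is None:
        raise ValueError("matrix carries no iBAQ values")
    bait_name = design.bait_name_of(bait_condition)
    bait_row = m.find_protein(bait_name)

    ratios = {}
    for j, sid in enumerate(m.samples):
        detected = m.observed[:, j] & (m.ibaq[:, j] > 0)
        med = float(np.median(m.ibaq[detected, j])) if detected.any() else np.nan
        ratios[sid] = m.ibaq[bait_row, j] / med if med and np.isfinite(med) else np.nan

    per_condition = {}
    for cond in design.conditions:
        vals = np.array([ratios[s] for s in design.samples_of(cond) if np.isfinite(ratios[s])])
        per_condition[cond] = {
            "mean_ratio": float(vals.mean()) if vals.size else float("nan"),
            "sem_ratio": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"),
            "n": int(vals.size),
        }
    ctrl_means = [
        v["mean_ratio"]
        for cond, v in per_condition.items()
        if set(design.frame.loc[design.frame["condition"] == cond, "role"]) == {"control"}
    ]
    bait_mean = per_condition[bait_condition]["mean_ratio"]
    flag = bool(ctrl_means and np.isfinite(bait_mean) and bait_mean <= max(ctrl_means))
    return {
        "bait": bait_name,
        "bait_condition": bait_condition,
        "per_sample_ratio": ratios,
        "per_condition": per_condition,
        "low_enrichment_flag": flag,
    }


def write_overlap_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))
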