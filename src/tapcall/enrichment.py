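"""s0-moderated two-sample statistic and permutation-based FDR classes.

Each bait-versus-control comparison is scored per protein with a moderated
Welch-style statistic in the SAM (significance analysis of microarrays)
convention::

    d = (mean_bait - mean_ctrl) / (sqrt(s_b^2/n_b + s_c^2/n_c) + s0)

where ``s0`` (default 1) damps the significance of tiny fold changes with
small variance.  Significance is assessed against a permutation null built by
reshuffling the bait/control labels of the pooled samples: when the number of
distinct label assignments is small enough they are all enumerated
(deterministic), otherwise a seeded sample of distinct assignments is drawn.
The estimated FDR at a threshold t on |d| is

    FDR(t) = E_perm[ #{null |d| >= t} ] / max(1, #{observed |d| >= t})

monotonized to be non-increasing in t, with pi0 fixed at 1 (conservative).
Class A proteins exceed the smallest threshold with FDR <= 0.05; Class B
analogous at 0.10 — the two confidence tiers drawn as solid and dashed
significance lines on the volcano ("Hawaii") plots.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import LOG2_IMPUTED, QuantMatrix, SampleDesign

__all__ = [
    "ComparisonSpec",
    "moderated_welch_d",
    "moderated_welch_d_matrix",
    "permutation_null_distribution",
    "permutation_fdr_classify",
    "enrich",
    "volcano_table",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """Parameters of one bait-versus-control comparison."""

    bait_condition: str
    control_condition: str
    s0: float = 1.0
    fdr_class_a: float = 0.05
    fdr_class_b: float = 0.10
    n_permutations: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        for name in ("fdr_class_a", "fdr_class_b"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fdr_class_a > self.fdr_class_b:
            raise ValueError("fdr_class_a must be <= fdr_class_b")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


def moderated_welch_d(x_bait, x_ctrl, s0: float = 1.0) -> float:
    """Moderated Welch statistic for one protein.

    With ``s0=0`` this reduces exactly to the classical Welch t statistic.
    """
    xb = np.asarray(x_bait, dtype=float)
    xc = np.asarray(x_ctrl, dtype=float)
    if xb.size < 2 or xc.size < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    se = math.sqrt(xb.var(ddof=1) / xb.size + xc.var(ddof=1) / xc.size)
    if s0 == 0 and se == 0:
        raise ValueError("s0=0 with zero variance in both groups: statistic undefined")
    return float((xb.mean() - xc.mean()) / (se + s0))


def moderated_welch_d_matrix(B: np.ndarray, C: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized ``moderated_welch_d`` over rows of two (proteins x reps) blocks."""
    if B.shape[1] < 2 or C.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicate columns")
    se = np.sqrt(B.var(axis=1, ddof=1) / B.shape[1] + C.var(axis=1, ddof=1) / C.shape[1])
    denom = se + s0
    if s0 == 0 and (denom == 0).any():
        raise ValueError("s0=0 with zero variance rows: statistic undefined")
    return (B.mean(axis=1) - C.mean(axis=1)) / denom


def _label_assignments(n_total: int, n_bait: int, n_permutations: int, seed: int):
    """Distinct bait-column index sets for the permutation null.

    All C(n_total, n_bait) assignments are enumerated when they fit within
    ``n_permutations``; otherwise that many distinct assignments are sampled
    without replacement, always force-including the identity assignment
    (columns 0..n_bait-1) in the SAM convention.
    """
    n_all = math.comb(n_total, n_bait)
    if n_all < 2:
        raise ValueError("fewer than 2 distinct label assignments; permutation null impossible")
    identity = tuple(range(n_bait))
    if n_all <= n_permutations:
        return [tuple(c) for c in itertools.combinations(range(n_total), n_bait)], True
    rng = np.random.default_rng(seed)
    chosen = {identity}
    while len(chosen) < n_permutations:
        chosen.add(tuple(sorted(rng.choice(n_total, size=n_bait, replace=False).tolist())))
    return sorted(chosen), False


def permutation_null_distribution(
    m: QuantMatrix, spec: ComparisonSpec, design: SampleDesign
) -> tuple[np.ndarray, list[tuple[int, ...]], bool]:
    """Null |d| table: one row per label assignment, one column per protein.

    Returns ``(null_d, assignments, enumerated)`` where ``null_d`` has shape
    (n_assignments, n_proteins).
    """
    if m.scale_tag != LOG2_IMPUTED:
        raise ValueError("permutation null expects an imputed log2 matrix")
    bait_cols = m.column_matrix(design.samples_of(spec.bait_condition))
    ctrl_cols = m.column_matrix(design.samples_of(spec.control_condition))
    pooled = np.hstack([bait_cols, ctrl_cols])
    n_bait = bait_cols.shape[1]
    n_total = pooled.shape[1]
    assignments, enumerated = _label_assignments(
        n_total, n_bait, spec.n_permutations, spec.seed
    )
    null = np.empty((len(assignments), m.n_proteins))
    all_idx = set(range(n_total))
    for k, combo in enumerate(assignments):
        rest = sorted(all_idx - set(combo))
        null[k] = moderated_welch_d_matrix(pooled[:, list(combo)], pooled[:, rest], spec.s0)
    return null, assignments, enumerated


def _fdr_curve(obs_abs: np.ndarray, null_abs: np.ndarray, n_perms: int):
    """Estimated FDR at each candidate threshold (the sorted observed |d|).

    Returns thresholds ascending and the monotonized (non-increasing in t)
    FDR estimates.
    """
    thresholds = np.sort(obs_abs)
    null_sorted = np.sort(null_abs)
    # tail counts via binary search on the sorted arrays
    null_tail = null_abs.size - np.searchsorted(null_sorted, thresholds, side="left")
    obs_sorted = np.sort(obs_abs)
    obs_tail = obs_abs.size - np.searchsorted(obs_sorted, thresholds, side="left")
    fdr = (null_tail / n_perms) / np.maximum(1, obs_tail)
    fdr = np.clip(fdr, 0.0, 1.0)
    # monotonize non-increasing in t: the operative FDR at threshold t is the
    # best raw estimate achievable at any threshold <= t (running min over
    # ascending thresholds), so raising t can never worsen the estimate
    fdr = np.minimum.accumulate(fdr)
    return thresholds, fdr


def _realized_threshold(thresholds: np.ndarray, fdr: np.ndarray, level: float) -> float:
    ok = fdr <= level
    return float(thresholds[ok][0]) if ok.any() else math.inf


def permutation_fdr_classify(
    observed_d: np.ndarray,
    null_d: np.ndarray,
    spec: ComparisonSpec,
    index: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Assign Class A/B membership from observed and null |d| tables.

    Returns a frame with columns ``d_stat``, ``perm_p``, ``fdr_class``,
    ``threshold_d_A`` and ``threshold_d_B``.  ``perm_p`` is the pooled
    permutation p-value ``(1 + #{null |d| >= |d_i|}) / (1 + N_null)``.
    """
    observed_d = np.asarray(observed_d, dtype=float)
    if observed_d.size == 0:
        raise ValueError("empty observed statistic set")
    obs_abs = np.abs(observed_d)
    null_abs = np.abs(np.asarray(null_d, dtype=float)).ravel()
    n_perms = np.asarray(null_d).shape[0]
    thresholds, fdr = _fdr_curve(obs_abs, null_abs, n_perms)
    t_a = _realized_threshold(thresholds, fdr, spec.fdr_class_a)
    t_b = _realized_threshold(thresholds, fdr, spec.fdr_class_b)

    null_sorted = np.sort(null_abs)
    ge_counts = null_abs.size - np.searchsorted(null_sorted, obs_abs, side="left")
    perm_p = (1.0 + ge_counts) / (1.0 + null_abs.size)

    fdr_class = np.where(obs_abs >= t_a, "A", np.where(obs_abs >= t_b, "B", "none"))
    return pd.DataFrame(
        {
            "d_stat": observed_d,
            "perm_p": perm_p,
            "fdr_class": fdr_class,
            "threshold_d_A": t_a,
            "threshold_d_B": t_b,
        },
        index=index,
    )


def enrich(m: QuantMatrix, design: SampleDesign, spec: ComparisonSpec) -> pd.DataFrame:
    """Full co-enrichment analysis of one bait-versus-control comparison.

    Returns one row per protein (indexed by group id) with group means,
    log2 fold change, moderated statistic, permutation p-value and FDR class.
    Metadata (realized thresholds, permutation count, enumeration flag) is
    attached in ``DataFrame.attrs``.
    """
    bait_block = m.column_matrix(design.samples_of(spec.bait_condition))
    ctrl_block = m.column_matrix(design.samples_of(spec.control_condition))
    d_obs = moderated_welch_d_matrix(bait_block, ctrl_block, spec.s0)
    null, assignments, enumerated = permutation_null_distribution(m, spec, design)
    res = permutation_fdr_classify(d_obs, null, spec, index=pd.Index(m.group_ids, name="protein"))
    res.insert(0, "mean_bait", bait_block.mean(axis=1))
    res.insert(1, "mean_ctrl", ctrl_block.mean(axis=1))
    res.insert(2, "log2fc", res["mean_bait"] - res["mean_ctrl"])
    res.attrs.update(
        {
            "bait_condition": spec.bait_condition,
            "control_condition": spec.control_condition,
            "s0": spec.s0,
            "fdr_class_a": spec.fdr_class_a,
            "fdr_class_b": spec.fdr_class_b,
            "n_assignments": len(assignments),
            "enumerated": enumerated,
            "threshold_d_A": float(res["threshold_d_A"].iloc[0]),
            "threshold_d_B": float(res["threshold_d_B"].iloc[0]),
        }
    )
    return res


def volcano_table(res: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano coordinates: (log2fc, -log10 perm_p, fdr_class)."""
    return pd.DataFrame(
        {
            "log2fc": res["log2fc"],
            "neg_log10_p": -np.log10(res["perm_p"]),
            "fdr_class": res["fdr_class"],
        },
        index=res.index,
    )
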