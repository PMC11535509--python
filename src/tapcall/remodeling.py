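"""Interactome-remodeling comparison across genetic perturbations.

Each perturbed condition's interactor set is compared against the control
interactome on the union of both sets: preys present only in the condition
are *gained*, only in control *lost*, in both *shared*; the three
percentages sum to 100 per condition.  The per-condition log2 fold changes
of the pooled interactor universe are assembled into a matrix and clustered
hierarchically (Euclidean distance, complete linkage), and the TAP samples
themselves are summarized by PCA on the imputed log2 intensity matrix
(samples as observations, centering per protein, no variance scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .quant import QuantMatrix, SampleDesign

__all__ = [
    "compare_to_control",
    "remodeling_summary",
    "log2fc_matrix",
    "ClusteredMatrix",
    "hclust_complete_euclidean",
    "pca_samples",
]


def compare_to_control(control_set: set, condition_set: set) -> dict:
    """Gained/shared/lost split of a condition's interactors versus control.

    Percentages are taken over the union of the two sets.
    """
    control_set, condition_set = set(control_set), set(condition_set)
    union = control_set | condition_set
    if not union:
        raise ValueError("both interactor sets are empty; comparison undefined")
    gained = condition_set - control_set
    lost = control_set - condition_set
    shared = control_set & condition_set
    n = len(union)
    return {
        "gained_pct": 100.0 * len(gained) / n,
        "shared_pct": 100.0 * len(shared) / n,
        "lost_pct": 100.0 * len(lost) / n,
        "gained": sorted(gained),
        "shared": sorted(shared),
        "lost": sorted(lost),
        "union_size": n,
    }


def remodeling_summary(control_set: set, condition_sets: dict[str, set]) -> pd.DataFrame:
    """One gained/shared/lost row per perturbed condition."""
    rows = []
    for cond, s in condition_sets.items():
        row = compare_to_control(control_set, s)
        row["condition"] = cond
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


def log2fc_matrix(enr_by_condition: dict[str, pd.DataFrame], universe) -> pd.DataFrame:
    """Preys x conditions matrix of log2 fold changes.

    ``universe`` is the prey list forming the rows (typically the union of
    interactors across conditions).  A prey absent from a condition's
    comparison yields a missing (NaN) cell; downstream clustering decides the
    fill policy.  Cells are carried through from the enrichment tables, never
    recomputed.
    """
    if len(enr_by_condition) < 2:
        raise ValueError("need >= 2 conditions")
    universe = list(dict.fromkeys(universe))
    data = {}
    for cond, enr in enr_by_condition.items():
        col = enr["log2fc"].reindex(universe)
        data[cond] = col
    return pd.DataFrame(data, index=pd.Index(universe, name="prey"))


@dataclass
class ClusteredMatrix:
    """Row-clustered matrix: reordered values plus the merge record."""

    data: pd.DataFrame          # rows in leaf order
    leaf_order: list            # row labels, leaf order of the dendrogram
    merges: np.ndarray          # scipy linkage matrix (Z)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _pairwise_complete_euclidean(X: np.ndarray) -> np.ndarray:
    """Euclidean distance on shared (both-observed) cells, rescaled to full dimension.

    d(i,j) = sqrt( p * mean over shared cells of (x_i - x_j)^2 )
    """
    n, p = X.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(X[i]) & np.isfinite(X[j])
            k = int(both.sum())
            if k == 0:
                raise ValueError(
                    f"rows {i} and {j} share no observed cells; pairwise-complete distance undefined"
                )
            diff = X[i, both] - X[j, both]
            D[i, j] = D[j, i] = np.sqrt(p * (diff**2).mean())
    return D


def hclust_complete_euclidean(matrix: pd.DataFrame, missing: str = "zero-fill") -> ClusteredMatrix:
    """Complete-linkage agglomeration of rows under Euclidean distance.

    ``missing`` is either ``"zero-fill"`` (NaN cells treated as 0, the
    default) or ``"pairwise-complete"`` (distances over shared cells, scaled
    back to full dimension).  Returns the merge record and leaf order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    X = matrix.to_numpy(dtype=float)
    if missing == "zero-fill":
        dvec = pdist(np.nan_to_num(X, nan=0.0), metric="euclidean")
    elif missing == "pairwise-complete":
        dvec = squareform(_pairwise_complete_euclidean(X), checks=False)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    Z = linkage(dvec, method="complete")
    order = leaves_list(Z)
    labels = [matrix.index[i] for i in order]
    return ClusteredMatrix(data=matrix.iloc[order], leaf_order=labels, merges=Z)


def pca_samples(m: QuantMatrix, design: SampleDesign | None = None, n_components: int | None = None) -> dict:
    """PCA of TAP samples on the (imputed) log2 intensity matrix.

    Samples are the observations, proteins the features; features are
    mean-centered (per protein) and not scaled.  Returns sample coordinates
    and variance-explained fractions, sorted descending.
    """
    X = m.values.T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("PCA expects a fully observed (imputed) matrix")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(m.samples, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    if design is not None:
        frame = frame.join(design.frame.set_index("sample_id")[["condition", "role"]])
    return {
        "coordinates": frame,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }
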