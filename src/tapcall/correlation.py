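"""Local and global Pearson-correlation interactor classifiers (Classes C/D).

Intensity profiles of truly interacting proteins track the bait's profile
across purifications.  Two classifiers exploit this:

* **local** (Class C): Pearson correlation between prey and bait profiles
  across one bait TAP + control TAP pair of sample sets; preys at or above a
  configured threshold (default 0.6) are called.  The mean local correlation
  of Class A interactors is derived and reported alongside, but never
  auto-applied as the threshold.
* **global** (Class D): Pearson correlation across *all* samples of all
  conditions, significance-controlled at a permutation FDR (default 0.05).
  The null is built by shuffling each prey's profile across sample positions
  (the statistic is a profile correlation, not a group contrast, so profile
  shuffling — not label relabeling — is the matching null).  Class D is
  one-sided on positive r, since co-enrichment with the bait is directional.

Correlations are computed on the imputed log2 matrix.  A constant profile
has no defined correlation: such pairs get NaN and are excluded from both
classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .quant import QuantMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "LocalThresholdConfig",
    "pearson_profile_correlation",
    "local_correlations",
    "derive_local_threshold",
    "classify_local",
    "global_correlation_classify",
    "correlate",
]


@dataclass(frozen=True)
class LocalThresholdConfig:
    """Operative Class C threshold plus the reported Class A derived mean."""

    threshold: float = 0.6
    derived_class_a_mean: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError(f"threshold must lie in (0, 1], got {self.threshold}")


def pearson_profile_correlation(prey_profile, bait_profile) -> float:
    """Standard Pearson r between two equal-length intensity profiles.

    Returns NaN (pair not evaluable) when either profile is constant.
    """
    x = np.asarray(prey_profile, dtype=float)
    y = np.asarray(bait_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("profiles must have length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        logger.warning("constant profile: correlation not evaluable")
        return math.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _rowwise_pearson(values: np.ndarray, bait: np.ndarray) -> np.ndarray:
    """Pearson r of every row of ``values`` against the vector ``bait``.

    Rows with zero variance yield NaN.
    """
    bc = bait - bait.mean()
    bnorm = np.sqrt((bc**2).sum())
    if bnorm == 0:
        raise ValueError("constant bait profile: correlations undefined")
    vc = values - values.mean(axis=1, keepdims=True)
    vnorm = np.sqrt((vc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ bc) / (vnorm * bnorm)
    r[vnorm == 0] = np.nan
    return r


def local_correlations(
    m: QuantMatrix, design: SampleDesign, bait_condition: str, control_condition: str
) -> pd.Series:
    """Per-prey Pearson r against the bait row across bait + control samples."""
    sids = design.samples_of(bait_condition) + design.samples_of(control_condition)
    cols = m.column_matrix(sids)
    bait_row = m.find_protein(design.bait_name_of(bait_condition))
    r = _rowwise_pearson(cols, cols[bait_row])
    return pd.Series(r, index=pd.Index(m.group_ids, name="protein"), name="r_local")


def derive_local_threshold(
    class_a_preys, r_local: pd.Series, cfg: LocalThresholdConfig | None = None
) -> LocalThresholdConfig:
    """Record the mean local correlation of Class A interactors.

    The mean is reported in ``derived_class_a_mean``; the operative threshold
    stays whatever the configuration says (default 0.6).
    """
    cfg = cfg or LocalThresholdConfig()
    preys = [p for p in class_a_preys if p in r_local.index]
    if not preys:
        logger.warning("empty Class A set: derived local-correlation mean unavailable")
        return replace(cfg, derived_class_a_mean=None)
    vals = r_local.loc[preys].dropna()
    if vals.empty:
        return replace(cfg, derived_class_a_mean=None)
    return replace(cfg, derived_class_a_mean=float(vals.mean()))


def classify_local(r_local: pd.Series, cfg: LocalThresholdConfig) -> pd.Series:
    """Class C membership: ``r_local >= threshold`` (boundary inclusive)."""
    return (r_local >= cfg.threshold).fillna(False).rename("class_c")


def global_correlation_classify(
    m: QuantMatrix,
    design: SampleDesign,
    bait: str,
    fdr: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Class D calling: global correlation with a permutation FDR.

    ``bait`` is the bait protein name (matched by group id, any group
    identifier, or gene symbol).  For each permutation every prey profile is
    independently shuffled across sample positions and re-correlated with the
    (unshuffled) bait profile.  FDR(t) over thresholds t on r is

        FDR(t) = E_perm[#{r* >= t}] / max(1, #{observed r >= t})

    monotonized non-increasing in t; Class D = r >= the smallest t with
    FDR(t) <= ``fdr``.  Returns columns ``r_global``, ``q_global``,
    ``class_d``.
    """
    if n_permutations < 50:
        logger.warning("n_permutations=%d < 50: global FDR estimate will be coarse", n_permutations)
    if len(design.conditions) < 2:
        raise ValueError("global correlation needs >= 2 conditions")
    values = m.values
    bait_row = m.find_protein(bait)
    bait_profile = values[bait_row]
    r_obs = _rowwise_pearson(values, bait_profile)

    rng = np.random.default_rng(seed)
    n_prot, n_samp = values.shape
    null_counts_at = np.sort(r_obs[np.isfinite(r_obs)])  # ascending candidate thresholds
    tail_null = np.zeros(null_counts_at.size)
    for _ in range(n_permutations):
        order = np.argsort(rng.random((n_prot, n_samp)), axis=1)
        shuffled = np.take_along_axis(values, order, axis=1)
        r_null = _rowwise_pearson(shuffled, bait_profile)
        r_null = np.sort(r_null[np.isfinite(r_null)])
        tail_null += r_null.size - np.searchsorted(r_null, null_counts_at, side="left")
    tail_null /= n_permutations

    obs_sorted = null_counts_at
    tail_obs = obs_sorted.size - np.searchsorted(obs_sorted, null_counts_at, side="left")
    curve = np.clip(tail_null / np.maximum(1, tail_obs), 0.0, 1.0)
    # running min over ascending thresholds: non-increasing in t
    curve = np.minimum.accumulate(curve)
    ok = curve <= fdr
    t_d = float(obs_sorted[ok][0]) if ok.any() else math.inf

    # per-prey q value: monotonized FDR estimate at the prey's own r
    pos = np.searchsorted(obs_sorted, r_obs, side="left")
    q = np.full(n_prot, np.nan)
    finite = np.isfinite(r_obs)
    q[finite] = curve[np.clip(pos[finite], 0, curve.size - 1)]

    class_d = np.zeros(n_prot, dtype=bool)
    class_d[finite] = r_obs[finite] >= t_d
    out = pd.DataFrame(
        {"r_global": r_obs, "q_global": q, "class_d": class_d},
        index=pd.Index(m.group_ids, name="protein"),
    )
    out.attrs.update({"threshold_r_D": t_d, "fdr": fdr, "n_permutations": n_permutations})
    return out


def correlate(
    m: QuantMatrix,
    design: SampleDesign,
    bait_condition: str,
    control_condition: str,
    cfg: LocalThresholdConfig | None = None,
    class_a_preys=(),
    fdr_global: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, LocalThresholdConfig]:
    """Run both correlation classifiers for one bait.

    Returns the merged per-prey table (r_local, r_global, q_global, class_c,
    class_d, self_flag) and the threshold config with the derived Class A
    mean filled in.
    """
    cfg = cfg or LocalThresholdConfig()
    bait_name = design.bait_name_of(bait_condition)
    r_local = local_correlations(m, design, bait_condition, control_condition)
    cfg = derive_local_threshold(class_a_preys, r_local, cfg)
    class_c = classify_local(r_local, cfg)
    glob = global_correlation_classify(
        m, design, bait_name, fdr=fdr_global, n_permutations=n_permutations, seed=seed
    )
    bait_row = m.find_protein(bait_name)
    self_flag = np.zeros(m.n_proteins, dtype=bool)
    self_flag[bait_row] = True
    table = pd.DataFrame(
        {
            "r_local": r_local,
            "r_global": glob["r_global"],
            "q_global": glob["q_global"],
            "class_c": class_c,
            "class_d": glob["class_d"],
            "self_flag": self_flag,
        }
    )
    table.attrs.update(glob.attrs)
    table.attrs["local_threshold"] = cfg.threshold
    table.attrs["derived_class_a_mean"] = cfg.derived_class_a_mean
    return table, cfg
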