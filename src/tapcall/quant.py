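"""Reading, filtering, transforming and imputing TAP-MS quantification tables.

The central container is :class:`QuantMatrix`, a proteins x samples matrix of
label-free quantification (LFQ) intensities together with an explicit
missingness mask and per-protein flags.  The dialect read and written here
follows the MaxQuant ``proteinGroups.txt`` convention: tab-separated, one row
per protein group, per-sample columns named ``LFQ intensity <sample>`` (and
optionally ``iBAQ <sample>``), and ``+``/blank flag columns ``Reverse``,
``Potential contaminant`` and ``Only identified by site``.  Zero intensities
and blank cells are both treated as missing, because MaxQuant writes 0 for
proteins it could not quantify in a sample.

Missing values are imputed, per sample, from a normal distribution shifted
1.8 standard deviations below the observed mean with a width of 0.3 observed
standard deviations — the standard left-censored (missing-not-at-random)
imputation for label-free proteomics.  The ``observed`` mask is never altered
by imputation, so downstream code can always distinguish measured from
imputed cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_LINEAR = "raw-linear"
LOG2 = "log2"
LOG2_IMPUTED = "log2-imputed"

_FLAG_COLUMNS = {
    "is_reverse": "Reverse",
    "is_contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group: identifiers plus quality/annotation flags.

    ``group_id`` is the leading majority-protein identifier; ``all_ids``
    holds every identifier of the group (semicolon-split in the file
    dialect).  ``is_mito`` is tri-state: None until annotated.
    """

    group_id: str
    all_ids: tuple[str, ...]
    gene_symbol: str | None = None
    is_reverse: bool = False
    is_contaminant: bool = False
    only_by_site: bool = False
    is_mito: bool | None = None

    def __post_init__(self) -> None:
        if not self.group_id:
            raise ValueError("group_id must be non-empty")
        if not self.all_ids or self.all_ids[0] != self.group_id:
            raise ValueError("group_id must be the first element of all_ids")
        for flag in ("is_reverse", "is_contaminant", "only_by_site"):
            if not isinstance(getattr(self, flag), (bool, np.bool_)):
                raise TypeError(f"{flag} must be boolean")

    def matches(self, name: str) -> bool:
        """True if *name* equals any identifier of the group or the gene symbol."""
        return name in self.all_ids or (self.gene_symbol is not None and name == self.gene_symbol)


@dataclass(frozen=True)
class AnnotationSet:
    """A named set of protein identifiers (e.g. a curated mitochondrial list)."""

    ids: frozenset[str]
    name: str

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"annotation set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "AnnotationSet":
        """Load one identifier per line; blank lines and ``#`` comments ignored.

        Duplicate entries are rejected: a curated list should not repeat ids.
        """
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        if len(set(lines)) != len(lines):
            raise ValueError(f"duplicate identifiers in annotation file {path}")
        return cls(ids=frozenset(lines), name=name or Path(path).stem)


class SampleDesign:
    """Maps samples to (condition, replicate, bait/control role).

    A *bait* condition is a set of TAP replicates from a cell line expressing
    one tagged bait; the *control* condition is the parental (untagged) line.
    """

    COLUMNS = ("sample_id", "condition", "replicate", "role", "bait_name")

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.copy()
        missing = [c for c in ("sample_id", "condition", "replicate", "role") if c not in frame.columns]
        if missing:
            raise ValueError(f"sample design missing columns: {missing}")
        if "bait_name" not in frame.columns:
            frame["bait_name"] = None
        frame["bait_name"] = frame["bait_name"].where(frame["bait_name"].notna(), None)
        frame["replicate"] = frame["replicate"].astype(int)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids in design: {dup}")
        if (frame["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        bad_role = set(frame["role"]) - {"bait", "control"}
        if bad_role:
            raise ValueError(f"unknown roles in design: {sorted(bad_role)}")
        for cond, grp in frame.groupby("condition"):
            roles = set(grp["role"])
            if roles == {"bait"}:
                names = {b for b in grp["bait_name"] if b}
                if len(names) != 1:
                    raise ValueError(
                        f"bait condition {cond!r} must carry exactly one bait_name, got {sorted(names)}"
                    )
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        sel = self.frame.loc[self.frame["condition"] == condition, "sample_id"]
        if sel.empty:
            raise KeyError(f"condition {condition!r} not in design")
        return sel.tolist()

    def bait_name_of(self, condition: str) -> str:
        grp = self.frame[self.frame["condition"] == condition]
        if grp.empty:
            raise KeyError(f"condition {condition!r} not in design")
        names = {b for b in grp["bait_name"] if b}
        if len(names) != 1:
            raise ValueError(f"condition {condition!r} has no unique bait_name")
        return names.pop()


@dataclass
class QuantMatrix:
    """Proteins x samples intensity matrix with missingness mask and flags.

    ``values`` holds NaN at missing cells until imputation; the ``observed``
    mask is authoritative and survives imputation unchanged.  ``scale_tag``
    tracks the processing stage (raw-linear -> log2 -> log2-imputed).
    """

    proteins: list[ProteinRecord]
    samples: list[str]
    values: np.ndarray
    observed: np.ndarray
    ibaq: np.ndarray | None = None
    scale_tag: str = RAW_LINEAR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        shape = (len(self.proteins), len(self.samples))
        if self.values.shape != shape or self.observed.shape != shape:
            raise ValueError(f"matrix shape {self.values.shape} != (proteins, samples) {shape}")
        if self.ibaq is not None:
            self.ibaq = np.asarray(self.ibaq, dtype=float)
            if self.ibaq.shape != shape:
                raise ValueError("ibaq matrix shape mismatch")
        if self.scale_tag not in (RAW_LINEAR, LOG2, LOG2_IMPUTED):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == RAW_LINEAR and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("raw-linear matrix contains negative values")
        if self.scale_tag in (LOG2, LOG2_IMPUTED) and not np.isfinite(self.values[self.observed]).all():
            raise ValueError("log2 matrix contains non-finite observed values")

    # -- lookups ------------------------------------------------------------

    @property
    def group_ids(self) -> list[str]:
        return [p.group_id for p in self.proteins]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def find_protein(self, name: str) -> int:
        """Row index of the protein matching *name* by group id, any id, or gene symbol."""
        for i, p in enumerate(self.proteins):
            if p.group_id == name:
                return i
        for i, p in enumerate(self.proteins):
            if p.matches(name):
                return i
        raise KeyError(f"protein {name!r} not found in matrix")

    def subset_rows(self, keep: np.ndarray) -> "QuantMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return QuantMatrix(
            proteins=[self.proteins[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx].copy(),
            observed=self.observed[idx].copy(),
            ibaq=None if self.ibaq is None else self.ibaq[idx].copy(),
            scale_tag=self.scale_tag,
        )

    def column_matrix(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.values[:, [self.sample_index(s) for s in sample_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_ids, columns=self.samples)


# ---------------------------------------------------------------------------
# Parsing and writing the protein-groups dialect


def parse_protein_groups(path: str | Path, design: SampleDesign) -> QuantMatrix:
    """Parse a MaxQuant-style protein-groups TSV into a raw-linear QuantMatrix.

    Requires an ``LFQ intensity <sample_id>`` column for every design sample.
    Zeros and blanks become missing cells; ``+`` flags map to True.  iBAQ
    columns are attached when present for all design samples.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = "Majority protein IDs"
    if id_col not in table.columns:
        raise ValueError(f"{path}: missing required column {id_col!r}")
    lfq_cols = {}
    for sid in design.sample_ids:
        col = f"LFQ intensity {sid}"
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r} required by the sample design")
        lfq_cols[sid] = col
    ibaq_cols = {sid: f"iBAQ {sid}" for sid in design.sample_ids}
    have_ibaq = all(c in table.columns for c in ibaq_cols.values())

    genes = table["Gene names"] if "Gene names" in table.columns else None
    proteins: list[ProteinRecord] = []
    for i, raw in enumerate(table[id_col]):
        ids = tuple(s.strip() for s in str(raw).split(";") if s.strip())
        if not ids:
            raise ValueError(f"{path}: row {i} has an empty {id_col!r} cell")
        gene = None
        if genes is not None and str(genes.iloc[i]).strip():
            gene = str(genes.iloc[i]).split(";")[0].strip()
        flags = {}
        for attr, col in _FLAG_COLUMNS.items():
            cell = str(table[col].iloc[i]).strip() if col in table.columns else ""
            flags[attr] = cell == "+"
        proteins.append(ProteinRecord(group_id=ids[0], all_ids=ids, gene_symbol=gene, **flags))

    def numeric(colname: str) -> np.ndarray:
        out = np.full(len(table), np.nan)
        for i, cell in enumerate(table[colname]):
            cell = str(cell).strip()
            if cell in ("", "NaN", "nan"):
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: unreadable numeric cell {cell!r} at row {i}, column {colname!r}"
                ) from None
        return out

    values = np.column_stack([numeric(lfq_cols[sid]) for sid in design.sample_ids])
    observed = np.isfinite(values) & (values != 0.0)
    values[~observed] = np.nan
    ibaq = None
    if have_ibaq:
        ibaq = np.column_stack([numeric(ibaq_cols[sid]) for sid in design.sample_ids])
        ibaq[~np.isfinite(ibaq)] = 0.0
    return QuantMatrix(
        proteins=proteins,
        samples=list(design.sample_ids),
        values=values,
        observed=observed,
        ibaq=ibaq,
        scale_tag=RAW_LINEAR,
    )


def write_protein_groups(m: QuantMatrix, path: str | Path) -> None:
    """Write a raw-linear QuantMatrix back to the protein-groups TSV dialect.

    Values are formatted to 6 significant digits; missing cells as 0.
    """
    if m.scale_tag != RAW_LINEAR:
        raise ValueError("write_protein_groups expects a raw-linear matrix")
    cols: dict[str, list] = {
        "Majority protein IDs": [";".join(p.all_ids) for p in m.proteins],
        "Gene names": [p.gene_symbol or "" for p in m.proteins],
    }
    for j, sid in enumerate(m.samples):
        cols[f"LFQ intensity {sid}"] = [
            f"{v:.6g}" if obs else "0"
            for v, obs in zip(m.values[:, j], m.observed[:, j])
        ]
    if m.ibaq is not None:
        for j, sid in enumerate(m.samples):
            cols[f"iBAQ {sid}"] = [f"{v:.6g}" for v in m.ibaq[:, j]]
    for attr, col in _FLAG_COLUMNS.items():
        cols[col] = ["+" if getattr(p, attr) else "" for p in m.proteins]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(m: QuantMatrix, values_path: str | Path, mask_path: str | Path | None = None) -> None:
    """Export the numeric matrix (and optionally the missingness mask) as TSV."""
    m.to_frame().to_csv(values_path, sep="\t")
    if mask_path is not None:
        pd.DataFrame(m.observed, index=m.group_ids, columns=m.samples).astype(int).to_csv(
            mask_path, sep="\t"
        )


# ---------------------------------------------------------------------------
# Filters and transforms


def filter_flagged(m: QuantMatrix) -> QuantMatrix:
    """Drop decoy (reverse), contaminant and only-identified-by-site rows."""
    keep = np.array(
        [not (p.is_reverse or p.is_contaminant or p.only_by_site) for p in m.proteins]
    )
    out = m.subset_rows(keep)
    if out.n_proteins == 0:
        logger.warning("filter_flagged removed every protein")
    return out


def annotate_mitochondrial(m: QuantMatrix, ann: AnnotationSet, drop: bool = False) -> QuantMatrix:
    """Set ``is_mito`` from membership of any group identifier (or gene symbol).

    With ``drop=True`` the non-mitochondrial rows are removed as well.
    """
    proteins = []
    for p in m.proteins:
        hit = any(i in ann.ids for i in p.all_ids) or (
            p.gene_symbol is not None and p.gene_symbol in ann.ids
        )
        proteins.append(replace(p, is_mito=hit))
    out = QuantMatrix(
        proteins=proteins,
        samples=list(m.samples),
        values=m.values.copy(),
        observed=m.observed.copy(),
        ibaq=None if m.ibaq is None else m.ibaq.copy(),
        scale_tag=m.scale_tag,
    )
    if drop:
        out = out.subset_rows(np.array([p.is_mito for p in out.proteins], dtype=bool))
    return out


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    if m.scale_tag != RAW_LINEAR:
        raise ValueError(f"log2_transform expects raw-linear input, got {m.scale_tag}")
    obs_vals = m.values[m.observed]
    if (obs_vals < 0).any():
        raise ValueError("negative intensity encountered; cannot log-transform")
    if (obs_vals == 0).any():
        raise ValueError("zero intensity marked observed; zeros must be missing")
    values = np.where(m.observed, np.log2(np.where(m.observed, m.values, 1.0)), np.nan)
    return QuantMatrix(
        proteins=list(m.proteins),
        samples=list(m.samples),
        values=values,
        observed=m.observed.copy(),
        ibaq=None if m.ibaq is None else m.ibaq.copy(),
        scale_tag=LOG2,
    )


def replicate_presence_filter(
    m: QuantMatrix,
    design: SampleDesign,
    min_reps: int = 2,
    scope: str = "per-condition",
    conditions: Iterable[str] | None = None,
) -> QuantMatrix:
    """Keep proteins observed in >= ``min_reps`` replicates.

    ``scope='per-condition'`` (default) requires the quota in *every*
    condition considered; ``scope='any-condition'`` in at least one.  Passing
    ``conditions`` restricts the check to a subset (e.g. one bait/control
    pair), which is how the filter is applied per comparison in the pipeline.
    """
    if scope not in ("per-condition", "any-condition"):
        raise ValueError(f"unknown scope {scope!r}")
    if min_reps == 0:
        return m.subset_rows(np.ones(m.n_proteins, dtype=bool))
    conds = list(conditions) if conditions is not None else design.conditions
    counts = []
    for cond in conds:
        sids = design.samples_of(cond)
        if len(sids) < min_reps:
            raise ValueError(
                f"condition {cond!r} has {len(sids)} samples < min_reps={min_reps}; filter unsatisfiable"
            )
        cols = [m.sample_index(s) for s in sids]
        counts.append(m.observed[:, cols].sum(axis=1))
    counts_arr = np.column_stack(counts)
    if scope == "per-condition":
        keep = (counts_arr >= min_reps).all(axis=1)
    else:
        keep = (counts_arr >= min_reps).any(axis=1)
    return m.subset_rows(keep)


def impute_missing_downshifted(
    m: QuantMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> QuantMatrix:
    """Impute missing cells from a down-shifted normal, per sample column.

    For a column with observed mean mu and SD sigma (n-1 denominator), every
    missing cell draws independently from Normal(mu - shift*sigma,
    (width*sigma)^2).  The observed mask is left untouched, so imputed cells
    remain distinguishable.
    """
    if m.scale_tag != LOG2:
        raise ValueError(f"imputation expects a log2 matrix, got {m.scale_tag}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = m.values.copy()
    for j, sid in enumerate(m.samples):
        col_obs = m.observed[:, j]
        if col_obs.sum() < 2:
            raise ValueError(f"sample {sid!r} has fewer than 2 observed values; cannot impute")
        obs = values[col_obs, j]
        mu, sigma = obs.mean(), obs.std(ddof=1)
        n_missing = int((~col_obs).sum())
        if n_missing:
            values[~col_obs, j] = rng.normal(mu - shift * sigma, width * sigma, size=n_missing)
    return QuantMatrix(
        proteins=list(m.proteins),
        samples=list(m.samples),
        values=values,
        observed=m.observed.copy(),
        ibaq=None if m.ibaq is None else m.ibaq.copy(),
        scale_tag=LOG2_IMPUTED,
    )
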