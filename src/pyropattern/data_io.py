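"""Input containers, readers, scale conversion, sample filtering, cohort
merging and location-scale batch adjustment.

All downstream stages consume the containers defined here.  Expression is
tagged with its scale (``linear`` or ``log2``); stages that require log2
input check the tag rather than guessing from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SCALES = ("linear", "log2")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a scale tag and cohort labels.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row of ``values``.
    sample_ids
        Unique sample identifiers, one per column of ``values``.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        Either ``"linear"`` (TPM/FPKM-like, non-negative) or ``"log2"``.
    cohort
        Optional per-sample cohort label; defaults to a single cohort.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    cohort: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene_ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample_ids: {sorted(dupes)[:5]}")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "linear" and (self.values < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        if self.cohort is None:
            self.cohort = np.array(["cohort0"] * self.n_samples, dtype=object)
        else:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != (self.n_samples,):
                raise ValueError("cohort must give one label per sample")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            scale=self.scale,
            cohort=self.cohort.copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        cols = [pos[s] for s in samples]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            values=self.values[:, cols].copy(),
            scale=self.scale,
            cohort=self.cohort[cols].copy(),
        )

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount) copy; no-op if already log2."""
        if self.scale == "log2":
            return replace(self, values=self.values.copy(), cohort=self.cohort.copy())
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=np.log2(self.values + pseudocount),
            scale="log2",
            cohort=self.cohort.copy(),
        )


@dataclass
class ClinicalTable:
    """Per-sample survival annotation plus optional covariates.

    ``data`` is indexed by sample_id with columns ``time`` (days, > 0),
    ``event`` (0/1) and any further covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            raise ValueError("ClinicalTable data must be indexed by 'sample_id'")
        if not df.index.is_unique:
            raise ValueError("duplicate sample_ids in clinical table")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        times = df["time"].to_numpy(dtype=float)
        if np.isnan(times).any() or (times <= 0).any():
            raise ValueError("survival times must be positive and non-missing")
        events = df["event"].to_numpy(dtype=float)
        if not np.isin(events, (0.0, 1.0)).all():
            raise ValueError("event indicator must be binary 0/1")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing[:10]}")
        return ClinicalTable(self.data.loc[list(samples)].copy())


class GeneSetCollection:
    """Mapping of set name to an ordered, duplicate-free list of gene symbols."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        self._sets: dict[str, list[str]] = {}
        for name, members in sets.items():
            members = [str(m).strip() for m in members]
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(f"gene set {name!r}: duplicate members removed")
            if name in self._sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            self._sets[str(name)] = deduped

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a linear FPKM matrix to TPM (each column sums to 1e6)."""
    if m.scale != "linear":
        raise ValueError("fpkm_to_tpm requires a linear-scale matrix")
    if (m.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        bad = [m.sample_ids[j] for j in zero]
        raise ValueError(f"all-zero expression column(s): {bad[:10]}")
    tpm = m.values / colsums[np.newaxis, :] * 1e6
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=tpm,
        scale="linear",
        cohort=m.cohort.copy(),
    )


def filter_samples(
    c: ClinicalTable, min_days: float = 30.0
) -> tuple[ClinicalTable, list[str]]:
    """Drop samples with short follow-up or an ambiguous event indicator.

    Returns the filtered table and the list of removed sample ids.
    """
    df = c.data
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    ok_event = event.isin([0, 1])
    keep = (time >= min_days) & time.notna() & ok_event
    removed = list(df.index[~keep])
    if removed:
        logger.info("filter_samples removed %d samples", len(removed))
    out = df.loc[keep].copy()
    if out.empty:
        warnings.warn("filter_samples removed every sample")
        # construct an empty but well-formed table
        empty = pd.DataFrame(
            {"time": pd.Series(dtype=float), "event": pd.Series(dtype=int)}
        )
        empty.index.name = "sample_id"
        return ClinicalTable(empty), removed
    return ClinicalTable(out), removed


def merge_cohorts(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts column-wise on the intersection of their genes."""
    if not matrices:
        raise ValueError("merge_cohorts requires at least one matrix")
    scales = {m.scale for m in matrices}
    if len(scales) > 1:
        raise ValueError(f"cannot merge matrices on different scales: {scales}")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    dupes = _duplicates(all_samples)
    if dupes:
        raise ValueError(f"duplicate sample ids across cohorts: {sorted(dupes)[:10]}")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes shared by all cohorts")
    # keep the first matrix's gene order
    genes = [g for g in matrices[0].gene_ids if g in common]
    blocks = [m.subset_genes(genes).values for m in matrices]
    cohorts = np.concatenate([m.cohort for m in matrices])
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=all_samples,
        values=np.hstack(blocks),
        scale=matrices[0].scale,
        cohort=cohorts,
    )


def correct_batch(m: ExpressionMatrix) -> ExpressionMatrix:
    """Location-scale batch adjustment on log2 expression.

    Per gene, every cohort is standardized and rescaled to the pooled
    (within-cohort residual) moments, so per-gene per-cohort means agree
    across cohorts afterwards.  Deterministic, idempotent, and rank-
    preserving within each cohort.  This is not empirical-Bayes shrinkage;
    no cross-gene pooling is performed.
    """
    if m.scale != "log2":
        raise ValueError("correct_batch expects log2-scale expression")
    labels = np.asarray(m.cohort)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("batch correction needs at least two cohorts")
    for c in uniq:
        if (labels == c).sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 samples")

    x = m.values.astype(float).copy()
    n_total = x.shape[1]
    k = len(uniq)
    masks = [(labels == c) for c in uniq]
    means = np.column_stack([x[:, msk].mean(axis=1) for msk in masks])
    sds = np.column_stack([x[:, msk].std(axis=1, ddof=1) for msk in masks])
    ns = np.array([msk.sum() for msk in masks])

    grand_mean = x.mean(axis=1)
    # pooled within-cohort residual sd (ddof-consistent: fixed point of the map)
    pooled_sd = np.sqrt(((ns - 1)[np.newaxis, :] * sds**2).sum(axis=1) / (n_total - k))

    out = np.empty_like(x)
    n_degenerate = 0
    for j, msk in enumerate(masks):
        centered = x[:, msk] - means[:, j][:, np.newaxis]
        scale = np.ones(x.shape[0])
        ok = sds[:, j] > 0
        scale[ok] = pooled_sd[ok] / sds[ok, j]
        n_degenerate += int((~ok).sum())
        out[:, msk] = centered * scale[:, np.newaxis] + grand_mean[:, np.newaxis]
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} (gene, cohort) cells had zero variance; centered only"
        )
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=out,
        scale="log2",
        cohort=m.cohort.copy(),
    )


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty gene-set file: {path}")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        name = fields[0].strip()
        members = [f.strip() for f in fields[2:] if f.strip()]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        if len(set(members)) != len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r}")
        sets[name] = list(dict.fromkeys(members))
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_expression(
    expr_path: str | Path,
    cohort_path: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene_id``) and optional
    cohort map TSV (columns ``sample_id``, ``cohort``)."""
    df = pd.read_csv(expr_path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError("expression TSV must start with a 'gene_id' column")
    df = df.set_index("gene_id")
    if df.isna().any().any():
        raise ValueError("expression TSV contains missing values")
    cohort = None
    if cohort_path is not None:
        cmap = pd.read_csv(cohort_path, sep="\t")
        if not {"sample_id", "cohort"} <= set(cmap.columns):
            raise ValueError("cohort map needs 'sample_id' and 'cohort' columns")
        lookup = dict(zip(cmap["sample_id"].astype(str), cmap["cohort"].astype(str)))
        missing = [s for s in df.columns if s not in lookup]
        if missing:
            raise ValueError(f"samples missing from cohort map: {missing[:10]}")
        cohort = np.array([lookup[s] for s in df.columns], dtype=object)
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        scale=scale,
        cohort=cohort,
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time, event, covariates.

    Rows with unparsable time/event are kept as-is for ``filter_samples``
    to report; strictly invalid tables (duplicate ids) are rejected here.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise ValueError("clinical TSV needs 'sample_id', 'time', 'event' columns")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    if not df.index.is_unique:
        raise ValueError("duplicate sample_ids in clinical table")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    # validate through filter with min_days=0: drops only broken records
    table, removed = filter_samples(_UnvalidatedClinical(df), min_days=np.nextafter(0, 1))
    if removed:
        warnings.warn(f"dropped {len(removed)} clinical rows with invalid time/event")
    return table


class _UnvalidatedClinical:
    """Duck-typed stand-in so filter_samples can clean raw clinical frames."""

    def __init__(self, data: pd.DataFrame):
        self.data = data


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.data.to_csv(path, sep="\t")
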