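"""Data model and delimited-text I/O for expression and qPCR Ct data.

Three in-memory containers cover the whole workflow:

``ExpressionMatrix``
    gene x sample FPKM values from an RNA-seq quantification; input to the
    transcriptome screening stage.
``CtMatrix``
    gene x sample quantification-cycle (Ct) values from qPCR, technical
    replicates already collapsed to their arithmetic mean; input to every
    stability algorithm and to the validation utilities.
``StudyDesign``
    sample -> (factor, level) assignments, e.g. development stage or
    hair-follicle cycle phase, used to group samples for per-condition runs.

All files are plain UTF-8 delimited text (tab or comma, auto-detected from
the header).  Missing Ct cells are carried as explicit NaN markers and never
silently become zero; each downstream algorithm applies its own policy.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DesignMismatchError,
    DomainError,
    DuplicateIdError,
    MissingDataError,
    ShapeError,
)

CT_MAX = 45.0  # cycles; instruments stop well before this


def _detect_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    # tab wins when present: comma may legally appear inside quoted labels
    return "\t" if "\t" in header else ","


def _check_unique(ids: Iterable[str], kind: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DuplicateIdError(f"duplicate {kind} identifier(s): {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative FPKM values."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids, float

    def __post_init__(self) -> None:
        df = self.values
        genes = _check_unique(df.index, "gene")
        samples = _check_unique(df.columns, "sample")
        df.index = pd.Index(genes, name="gene")
        df.columns = pd.Index(samples, name="sample")
        if df.shape[1] < 2:
            raise ShapeError(
                f"need at least 2 samples for screening metrics, got {df.shape[1]}"
            )
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = df.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise DomainError(f"non-finite FPKM values in genes: {bad}")
        if (arr < 0).any():
            bad = df.index[(arr < 0).any(axis=1)].tolist()
            raise DomainError(f"negative FPKM values in genes: {bad}")
        self.values = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy())

    def to_file(self, path: str | Path, sep: str = "\t", float_format: str | None = None) -> None:
        self.values.to_csv(path, sep=sep, float_format=float_format)


@dataclass
class CtMatrix:
    """Gene x sample matrix of quantification-cycle values (cycles).

    ``replicate_depth`` records how many technical replicates were collapsed
    (by arithmetic mean) into each cell; 1 means the table was already flat.
    Missing cells are NaN and are reported by :meth:`missing_cells`.
    """

    ct: pd.DataFrame
    replicate_depth: int = 1

    def __post_init__(self) -> None:
        df = self.ct
        genes = _check_unique(df.index, "gene")
        samples = _check_unique(df.columns, "sample")
        df.index = pd.Index(genes, name="gene")
        df.columns = pd.Index(samples, name="sample")
        arr = df.to_numpy(dtype=float)
        observed = ~np.isnan(arr)
        if ((arr[observed] <= 0) | (arr[observed] > CT_MAX)).any():
            raise DomainError(f"Ct values must lie in (0, {CT_MAX}] cycles")
        if int(self.replicate_depth) < 1:
            raise DomainError("replicate_depth must be >= 1")
        self.replicate_depth = int(self.replicate_depth)
        self.ct = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape

    def missing_cells(self) -> list[tuple[str, str]]:
        mask = self.ct.isna()
        return [
            (g, s) for g in self.ct.index for s in self.ct.columns if mask.at[g, s]
        ]

    def require_complete(self) -> None:
        missing = self.missing_cells()
        if missing:
            raise MissingDataError(f"missing Ct cells: {missing}")

    def subset_samples(self, samples: Iterable[str]) -> "CtMatrix":
        return CtMatrix(self.ct[list(samples)].copy(), self.replicate_depth)

    def subset_genes(self, genes: Iterable[str]) -> "CtMatrix":
        return CtMatrix(self.ct.loc[list(genes)].copy(), self.replicate_depth)

    def drop_incomplete_samples(self) -> "CtMatrix":
        """Listwise missing-data policy: drop any sample with a missing Ct."""
        keep = self.ct.columns[~self.ct.isna().any(axis=0)]
        return CtMatrix(self.ct[keep].copy(), self.replicate_depth)

    def to_file(self, path: str | Path, sep: str = "\t", float_format: str | None = None) -> None:
        self.ct.to_csv(path, sep=sep, float_format=float_format)


@dataclass
class StudyDesign:
    """Sample -> level assignment for one or more experimental factors."""

    table: pd.DataFrame  # columns: sample, factor, level

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"sample", "factor", "level"}
        if not required.issubset(df.columns):
            raise DesignMismatchError(
                f"design table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        for col in ("sample", "factor", "level"):
            df[col] = df[col].astype(str).str.strip()
        dup = df.duplicated(subset=["sample", "factor"])
        if dup.any():
            pairs = df.loc[dup, ["sample", "factor"]].to_records(index=False).tolist()
            raise DesignMismatchError(
                f"sample assigned more than one level of the same factor: {pairs}"
            )
        self.table = df[["sample", "factor", "level"]]

    @classmethod
    def from_mapping(cls, factor: str, assignment: Mapping[str, str]) -> "StudyDesign":
        rows = [(s, factor, lv) for s, lv in assignment.items()]
        return cls(pd.DataFrame(rows, columns=["sample", "factor", "level"]))

    @property
    def factors(self) -> list[str]:
        return sorted(self.table["factor"].unique())

    def levels(self, factor: str) -> list[str]:
        sub = self.table[self.table["factor"] == factor]
        if sub.empty:
            raise DesignMismatchError(f"unknown factor: {factor!r}")
        return sorted(sub["level"].unique())

    def level_of(self, factor: str) -> dict[str, str]:
        sub = self.table[self.table["factor"] == factor]
        if sub.empty:
            raise DesignMismatchError(f"unknown factor: {factor!r}")
        return dict(zip(sub["sample"], sub["level"]))

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


@dataclass
class StabilitySeries:
    """Per-gene stability values from one algorithm.

    ``lower_is_stable`` is recorded so that rank aggregation can refuse to
    mix orientations; all four algorithms implemented here are oriented
    lower-is-more-stable.
    """

    algorithm: str
    values: pd.Series  # index gene, float
    lower_is_stable: bool = True
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = pd.Index([str(g).strip() for g in s.index], name="gene")
        if not np.isfinite(s.to_numpy()).all():
            raise DomainError(f"{self.algorithm}: non-finite stability values")
        _check_unique(s.index, "gene")
        self.values = s

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def ranking(self) -> pd.Series:
        """Integer ranks 1..G, most stable first; ties broken by gene id."""
        s = self.values if self.lower_is_stable else -self.values
        order = sorted(s.index, key=lambda g: (s[g], g))
        return pd.Series(
            np.arange(1, len(order) + 1), index=pd.Index(order, name="gene"), name="rank"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample FPKM table (first column gene ids, header samples).

    Rows containing any non-numeric cell are rejected with a
    :class:`~refstab.errors.DomainError` naming the offending genes.
    """
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)

    def _to_float(v):  # Python float() is correctly rounded, unlike the fast parser
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    body = df.apply(lambda col: col.map(_to_float))
    bad = df.index[body.isna().any(axis=1) | df.isna().any(axis=1)].tolist()
    if bad:
        raise DomainError(f"non-numeric FPKM cells in genes: {bad}")
    return ExpressionMatrix(body)


def read_ct_table(
    path: str | Path,
    layout: str = "wide",
    sep: str | None = None,
    allow_missing: bool = False,
) -> CtMatrix:
    """Read a Ct table.

    ``layout='wide'`` expects gene rows x sample columns.  ``layout='long'``
    expects columns ``gene, sample, replicate, ct`` and collapses technical
    replicates by arithmetic mean, recording ``replicate_depth`` as the
    maximum replicate count seen.
    """
    sep = sep or _detect_sep(path)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if df.isna().any().any() and not allow_missing:
            mask = df.isna()
            cells = [
                (str(g), str(s))
                for g in df.index
                for s in df.columns
                if mask.at[g, s]
            ]
            raise MissingDataError(f"empty Ct cell(s) for (gene, sample): {cells}")
        return CtMatrix(df.astype(float), replicate_depth=1)
    if layout == "long":
        df = pd.read_csv(path, sep=sep)
        needed = {"gene", "sample", "replicate", "ct"}
        if not needed.issubset(df.columns):
            raise ShapeError(
                f"long Ct table needs columns {sorted(needed)}, got {list(df.columns)}"
            )
        return collapse_replicates(df, allow_missing=allow_missing)
    raise ValueError(f"unknown layout: {layout!r}")


def collapse_replicates(long: pd.DataFrame, allow_missing: bool = False) -> CtMatrix:
    """Collapse a long gene/sample/replicate/ct frame to a mean-Ct matrix.

    The arithmetic mean over technical replicates is used; no outlier
    rejection is applied.  A gene-sample pair with zero observations is a
    :class:`~refstab.errors.MissingDataError` unless ``allow_missing``.
    """
    long = long.copy()
    long["gene"] = long["gene"].astype(str).str.strip()
    long["sample"] = long["sample"].astype(str).str.strip()
    long["ct"] = pd.to_numeric(long["ct"], errors="coerce")
    genes = list(dict.fromkeys(long["gene"]))
    samples = list(dict.fromkeys(long["sample"]))
    counts = long.dropna(subset=["ct"]).groupby(["gene", "sample"])["ct"].count()
    wide = (
        long.groupby(["gene", "sample"])["ct"].mean().unstack("sample")
        .reindex(index=genes, columns=samples)
    )
    if wide.isna().any().any() and not allow_missing:
        mask = wide.isna()
        cells = [(g, s) for g in genes for s in samples if mask.at[g, s]]
        raise MissingDataError(f"gene-sample pair(s) with zero Ct replicates: {cells}")
    depth = int(counts.max()) if len(counts) else 1
    return CtMatrix(wide, replicate_depth=depth)


def read_design(path: str | Path, sep: str | None = None) -> StudyDesign:
    sep = sep or _detect_sep(path)
    return StudyDesign(pd.read_csv(path, sep=sep, dtype=str))


def collapse_and_join(
    ct: CtMatrix, design: StudyDesign, factor: str
) -> dict[str, list[str]]:
    """Partition the CtMatrix samples into the factor's levels.

    Every sample of ``ct`` must carry exactly one level of ``factor``; the
    returned subsets are disjoint and their union is the sample set.
    """
    level_of = design.level_of(factor)
    missing = [s for s in ct.sample_ids if s not in level_of]
    if missing:
        raise DesignMismatchError(
            f"samples missing from design for factor {factor!r}: {missing}"
        )
    groups: dict[str, list[str]] = {}
    for s in ct.sample_ids:
        groups.setdefault(level_of[s], []).append(s)
    return groups


def series_to_frame(series_list: list[StabilitySeries]) -> pd.DataFrame:
    """Gene x algorithm table of stability values (column order preserved)."""
    return pd.DataFrame({s.algorithm: s.values for s in series_list})


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return {c: o[c].to_dict() for c in o.columns}
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(obj, indent=2, sort_keys=True, default=default)
    Path(path).write_text(text + "\n", encoding="utf-8")
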