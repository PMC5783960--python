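"""Readers, writers and in-memory containers for the screening pipeline.

The pipeline consumes a post-normalization (RMA-style, *unlogged*) expression
matrix, a sample sheet assigning each array to one of the four treatment
groups (young control YC, aged control AC, short-term ST and long-term LT
rescue), and optionally a GMT gene-set collection for category
overrepresentation.  All formats are plain tab-delimited text; missing
intensities are encoded as empty cells or ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical group labels, in display order.
DEFAULT_GROUPS: tuple[str, ...] = ("YC", "AC", "ST", "LT")

#: Column reserved for gene annotations in an expression matrix file.
ANNOTATION_COLUMN = "annotation"


@dataclass
class ExpressionStudy:
    """A genes x samples unlogged intensity matrix with group structure.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene id, one column per sample.
        Intensities are unlogged RMA-scale signals; ``NaN`` marks missing.
    group_of
        Series mapping sample id -> group label, aligned with the columns
        of ``values``.
    annotations
        Optional Series mapping gene id -> symbol/description.
    group_labels
        The declared set of group labels (default ``YC, AC, ST, LT``).
    """

    values: pd.DataFrame
    group_of: pd.Series
    annotations: pd.Series | None = None
    group_labels: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.group_of.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        self.group_of = self.group_of.reindex(self.values.columns)
        bad = sorted(set(self.group_of) - set(self.group_labels))
        if bad:
            raise ValueError(
                f"unknown group label(s) {bad}; declared groups are {list(self.group_labels)}"
            )
        vals = self.values.to_numpy(dtype=float)
        finite = np.isfinite(vals) | np.isnan(vals)
        if not finite.all():
            raise ValueError("intensities must be finite or missing")
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValueError("unlogged intensities must be > 0 where present")
        if self.annotations is not None:
            self.annotations = self.annotations.reindex(idx)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def group_columns(self) -> dict[str, list[str]]:
        """Sample ids per group label, in declared group order."""
        return {
            g: [s for s in self.samples if self.group_of[s] == g]
            for g in self.group_labels
        }

    def require_all_groups(self) -> None:
        empty = [g for g, cols in self.group_columns().items() if not cols]
        if empty:
            raise ValueError(f"group(s) with no samples: {empty}")

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionStudy":
        keep = pd.Index(gene_ids)
        ann = self.annotations.loc[keep] if self.annotations is not None else None
        return ExpressionStudy(
            values=self.values.loc[keep].copy(),
            group_of=self.group_of.copy(),
            annotations=ann,
            group_labels=self.group_labels,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO categories) with free-text descriptions."""

    categories: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
            self.categories[name] = frozenset(members)
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.categories)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and self.categories == other.categories
            and self.descriptions == other.descriptions
        )


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a sample->group Series."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    return pd.Series(sheet["group"].values, index=sheet["sample_id"].values, name="group")


def read_expression_matrix(
    path: str | Path,
    sample_sheet_path: str | Path,
    group_labels: Sequence[str] = DEFAULT_GROUPS,
) -> ExpressionStudy:
    """Read an expression TSV (first column gene id) plus its sample sheet.

    An optional ``annotation`` column in the matrix is split off as per-gene
    annotation.  Unparseable cells become missing values with a logged
    warning; structural problems (duplicate gene ids, samples absent from
    the sheet, undeclared group labels) raise ``ValueError``.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    annotations = None
    if ANNOTATION_COLUMN in raw.columns:
        annotations = raw.pop(ANNOTATION_COLUMN)
        annotations.name = ANNOTATION_COLUMN
    cleaned = raw.replace({"": np.nan, "NA": np.nan})
    values = cleaned.apply(pd.to_numeric, errors="coerce")
    n_bad = int((values.isna() & cleaned.notna()).sum().sum())
    if n_bad:
        logger.warning("%d unparseable cell(s) in %s treated as missing", n_bad, path)
    group_of = read_sample_sheet(sample_sheet_path)
    return ExpressionStudy(
        values=values,
        group_of=group_of,
        annotations=annotations,
        group_labels=tuple(group_labels),
    )


def write_expression_matrix(study: ExpressionStudy, path: str | Path) -> None:
    """Write the study matrix (and annotation column, if any) as TSV."""
    out = study.values.copy()
    out.index.name = "gene_id"
    if study.annotations is not None:
        out.insert(0, ANNOTATION_COLUMN, study.annotations)
    out.to_csv(path, sep="\t", na_rep="NA")


def write_sample_sheet(group_of: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": group_of.index, "group": group_of.values})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene ids, one set per line."""
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: category {name!r} has no genes")
            categories[name] = members
            descriptions[name] = desc
    return GeneSetCollection(categories=categories, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.categories:
            genes = sorted(collection.categories[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(
    records: pd.DataFrame,
    path: str | Path,
    sort_by: str | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write a result table as deterministic TSV.

    Column order is preserved; rows are optionally sorted by ``sort_by``
    (ties broken by the first column) so repeated calls are byte-identical.
    """
    out = records.copy()
    if sort_by is not None and len(out):
        tie = out.columns[0]
        by = [sort_by] if sort_by == tie else [sort_by, tie]
        out = out.sort_values(by=by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=float_format)
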