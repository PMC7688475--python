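"""Mixed-type clinical tables: typed variables, missingness profiling and filtering.

The universal input of the package is a :class:`MixedDataset`: an observation ×
variable grid in which every column is declared as binary, ordinal, categorical
or continuous and carries a role (feature, outcome or annotation).  Clinical
tables are almost never complete, so missing entries are first-class citizens:
they are tracked in an explicit boolean mask and every downstream stage keeps
row and column identifiers so results map back to the source records.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableMeta",
    "MixedDataset",
    "MissingnessProfile",
    "FilterReport",
    "DatasetFormatError",
    "DatasetValidationError",
    "DegenerateFilterError",
    "DEFAULT_MISSING_TOKENS",
    "read_dataset",
    "read_metadata",
    "missingness_profile",
    "filter_missing",
]

#: Tokens interpreted as missing entries when reading delimited text.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN", "?")

KINDS = ("binary", "ordinal", "categorical", "continuous")
ROLES = ("feature", "outcome", "annotation")


class DatasetFormatError(ValueError):
    """Malformed input file (missing header, undeclared column, bad sidecar)."""


class DatasetValidationError(ValueError):
    """Table entry inconsistent with the declared variable metadata."""


class DegenerateFilterError(ValueError):
    """Missingness filtering removed every column (or every row)."""


@dataclass(frozen=True)
class VariableMeta:
    """Declaration of one column of a mixed-type table.

    Parameters
    ----------
    name
        Column name, must match the table header.
    kind
        One of ``binary``, ``ordinal``, ``categorical``, ``continuous``.
    levels
        Ordered admissible nominal values.  Required for ordinal and
        categorical columns (order matters for ordinals), exactly two for
        binary, and absent for continuous columns.
    role
        ``feature`` columns enter the data space, ``outcome`` columns define
        classes/events, ``annotation`` columns are carried along for display.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    role: str = "feature"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DatasetFormatError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise DatasetFormatError(f"unknown variable role {self.role!r} for {self.name!r}")
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if self.kind == "continuous":
            if self.levels:
                raise DatasetFormatError(f"continuous variable {self.name!r} must not declare levels")
        elif self.kind == "binary":
            if self.levels is None or len(self.levels) != 2:
                raise DatasetFormatError(f"binary variable {self.name!r} must declare exactly 2 levels")
        else:  # ordinal / categorical
            if not self.levels:
                raise DatasetFormatError(f"{self.kind} variable {self.name!r} must declare >= 1 level")
        if self.levels is not None and len(set(self.levels)) != len(self.levels):
            raise DatasetFormatError(f"duplicate levels declared for {self.name!r}")

    @property
    def is_nominal(self) -> bool:
        return self.kind in ("binary", "ordinal", "categorical")


@dataclass
class MixedDataset:
    """Observation × typed-variable grid with an explicit missingness mask.

    ``values`` holds strings for nominal entries, floats for continuous ones
    and ``NaN`` wherever ``missing_mask`` is True.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    meta: list[VariableMeta]
    row_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_ids:
            self.row_ids = list(self.values.index)
        self.validate()

    # -- basic geometry ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def columns_of_kind(self, *kinds: str, roles: Sequence[str] | None = None) -> list[str]:
        return [
            m.name
            for m in self.meta
            if m.kind in kinds and (roles is None or m.role in roles)
        ]

    def validate(self) -> None:
        if len(self.meta) != self.n_cols:
            raise DatasetFormatError(
                f"metadata declares {len(self.meta)} variables but the table has {self.n_cols} columns"
            )
        names = [m.name for m in self.meta]
        if names != self.columns:
            raise DatasetFormatError("metadata order/names do not match table columns")
        if self.missing_mask.shape != self.values.shape:
            raise DatasetFormatError("missing mask shape does not match values")
        for m in self.meta:
            col = self.values[m.name]
            mask = self.missing_mask[m.name].to_numpy()
            observed = col[~mask]
            if m.is_nominal:
                bad = ~observed.astype(str).isin(m.levels)
                if bad.any():
                    row = observed.index[bad.to_numpy()][0]
                    raise DatasetValidationError(
                        f"value {observed.loc[row]!r} at row {row!r}, column {m.name!r} "
                        f"is not among declared levels {list(m.levels)}"
                    )
            else:
                try:
                    observed.astype(float)
                except (TypeError, ValueError) as exc:
                    raise DatasetValidationError(
                        f"non-numeric entry in continuous column {m.name!r}: {exc}"
                    ) from None

    # -- subsetting (ids preserved) ---------------------------------------
    def take_rows(self, index) -> "MixedDataset":
        return MixedDataset(
            values=self.values.loc[index].copy(),
            missing_mask=self.missing_mask.loc[index].copy(),
            meta=list(self.meta),
            row_ids=list(index),
        )

    def take_columns(self, names: Sequence[str]) -> "MixedDataset":
        names = list(names)
        return MixedDataset(
            values=self.values[names].copy(),
            missing_mask=self.missing_mask[names].copy(),
            meta=[m for m in self.meta if m.name in set(names)],
            row_ids=list(self.row_ids),
        )

    def to_csv(self, path: str | Path, missing_token: str = "") -> None:
        out = self.values.copy().astype(object)
        out[self.missing_mask] = missing_token
        out.to_csv(path, index=True, index_label="row_id")


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-row and per-column missing fractions of a dataset."""

    row_fractions: pd.Series
    column_fractions: pd.Series
    total_missing: int

    @property
    def overall_fraction(self) -> float:
        n = len(self.row_fractions) * len(self.column_fractions)
        return self.total_missing / n if n else 0.0


@dataclass(frozen=True)
class FilterReport:
    """Record of a missingness filtering pass."""

    delta_column: float
    delta_row: float
    dropped_columns: list[str]
    dropped_rows: list
    kept_columns: list[str]
    kept_rows: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=str, indent=2))


# ---------------------------------------------------------------------------
# reading


def read_metadata(meta_path: str | Path) -> list[VariableMeta]:
    """Load the JSON variable-metadata sidecar (list of declarations)."""
    raw = json.loads(Path(meta_path).read_text())
    if not isinstance(raw, list):
        raise DatasetFormatError("metadata sidecar must be a JSON list of variable declarations")
    metas = []
    for entry in raw:
        metas.append(
            VariableMeta(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                levels=tuple(str(v) for v in entry["levels"]) if entry.get("levels") else None,
                role=str(entry.get("role", "feature")),
            )
        )
    return metas


def write_metadata(meta: Sequence[VariableMeta], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"name": m.name, "kind": m.kind, "levels": list(m.levels) if m.levels else None, "role": m.role}
                for m in meta
            ],
            indent=2,
        )
    )


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_dataset(
    table_path: str | Path,
    meta_path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> MixedDataset:
    """Read a delimited table plus its metadata sidecar into a MixedDataset.

    The delimiter (comma or tab) is autodetected.  The first line must be a
    header declaring every column; columns absent from the sidecar are
    rejected.  Entries matching ``missing_tokens`` become missing cells.
    """
    meta = read_metadata(meta_path)
    text = Path(table_path).read_text()
    if not text.strip():
        raise DatasetFormatError(f"{table_path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(table_path, sep=delim, dtype=str, keep_default_na=False)

    declared = {m.name for m in meta}
    if "row_id" in df.columns and "row_id" not in declared:
        df = df.set_index("row_id")
    header = list(df.columns)
    undeclared = [c for c in header if c not in declared]
    if undeclared:
        raise DatasetFormatError(f"columns not declared in metadata sidecar: {undeclared}")
    if any(str(c).startswith("Unnamed") for c in header) or len(set(header)) != len(header):
        raise DatasetFormatError("table header is missing or malformed")
    # keep metadata in table column order, drop declared-but-absent columns
    meta = [m for m in meta if m.name in header]
    order = sorted(header, key=header.index)
    meta.sort(key=lambda m: order.index(m.name))
    df = df[[m.name for m in meta]]

    tokens = set(missing_tokens)
    mask = df.apply(lambda col: col.str.strip().isin(tokens))
    values = df.copy().astype(object)
    values[mask] = np.nan
    for m in meta:
        if m.kind == "continuous":
            col = pd.to_numeric(values[m.name], errors="coerce")
            bad = col.isna() & ~mask[m.name]
            if bad.any():
                row = values.index[bad.to_numpy()][0]
                raise DatasetValidationError(
                    f"non-numeric entry {values.loc[row, m.name]!r} at row {row!r}, "
                    f"continuous column {m.name!r}"
                )
            values[m.name] = col
    return MixedDataset(values=values, missing_mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# missingness


def missingness_profile(ds: MixedDataset) -> MissingnessProfile:
    """Fraction of missing entries per row and per column."""
    mask = ds.missing_mask.to_numpy()
    return MissingnessProfile(
        row_fractions=pd.Series(mask.mean(axis=1), index=ds.values.index),
        column_fractions=pd.Series(mask.mean(axis=0), index=ds.values.columns),
        total_missing=int(mask.sum()),
    )


def filter_missing(
    ds: MixedDataset,
    delta_column: float,
    delta_row: float,
) -> tuple[MixedDataset, FilterReport]:
    """Drop overly incomplete columns, then rows (the greedy two-pass rule).

    Columns whose missing fraction is strictly greater than ``delta_column``
    are removed first; row fractions are then recomputed on the surviving
    columns and rows strictly above ``delta_row`` are removed.  This is the
    simple suboptimal alternative to searching for the largest admissible
    submatrix, and it is idempotent.
    """
    for name, d in (("delta_column", delta_column), ("delta_row", delta_row)):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {d}")
    mask = ds.missing_mask
    col_frac = mask.mean(axis=0)
    keep_cols = [c for c in ds.columns if col_frac[c] <= delta_column]
    dropped_cols = [c for c in ds.columns if c not in set(keep_cols)]
    if not keep_cols:
        raise DegenerateFilterError("all columns exceed the column missingness threshold")
    row_frac = mask[keep_cols].mean(axis=1)
    keep_rows = row_frac.index[row_frac.to_numpy() <= delta_row]
    dropped_rows = [r for r in ds.values.index if r not in set(keep_rows)]
    if len(keep_rows) == 0:
        raise DegenerateFilterError("all rows exceed the row missingness threshold")
    out = ds.take_columns(keep_cols).take_rows(keep_rows)
    report = FilterReport(
        delta_column=delta_column,
        delta_row=delta_row,
        dropped_columns=dropped_cols,
        dropped_rows=dropped_rows,
        kept_columns=keep_cols,
        kept_rows=list(keep_rows),
    )
    return out, report
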