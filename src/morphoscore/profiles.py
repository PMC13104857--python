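"""Data model and I/O for single-cell image-based profile tables.

A profile table holds one row per segmented cell.  Columns whose names carry
the ``Metadata_`` prefix are per-cell annotations (treatment, well, plate,
phenotype label, gene, ...); every other column is a numeric morphology
feature.  This is the dominant layout in the image-based profiling ecosystem
(CellProfiler -> pycytominer style outputs), so tables written by upstream
pipelines load directly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_PREFIX = "Metadata_"

SelectorLike = Mapping[str, Union[str, int, float, Sequence]]

__all__ = [
    "METADATA_PREFIX",
    "ProfileTable",
    "PopulationSelector",
    "load_profiles",
    "write_profiles",
    "select_population",
]


class ProfileTable:
    """A single-cell profile table: metadata columns plus a numeric feature matrix.

    Parameters
    ----------
    data
        DataFrame with at least one feature column.  Metadata columns are
        identified by the ``Metadata_`` name prefix; all remaining columns
        must be numeric morphology features with unique names.
    validate
        Check the invariants on construction (numeric features, unique
        names, no missing feature values).  Disable only when wrapping a
        frame that was just produced by a validated operation.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        self._data = data
        if validate:
            self._validate()

    # -- invariants --------------------------------------------------------

    def _validate(self) -> None:
        cols = list(self._data.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate column names: {dupes}")
        feats = self.feature_columns
        if not feats:
            raise ValueError("table has zero feature columns")
        for col in feats:
            series = self._data[col]
            if not pd.api.types.is_numeric_dtype(series):
                bad = series[pd.to_numeric(series, errors="coerce").isna() & series.notna()]
                row = int(bad.index[0]) if len(bad) else "?"
                raise ValueError(
                    f"feature column {col!r} is not numeric (e.g. row {row})"
                )
            if series.isna().any():
                row = int(series.index[series.isna()][0])
                raise ValueError(
                    f"feature column {col!r} has a missing value at row {row}; "
                    "load with missing='drop' to discard incomplete cells"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self._data.columns if str(c).startswith(METADATA_PREFIX)]

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self._data.columns if not str(c).startswith(METADATA_PREFIX)]

    @property
    def metadata(self) -> pd.DataFrame:
        return self._data[self.metadata_columns]

    @property
    def features(self) -> pd.DataFrame:
        return self._data[self.feature_columns]

    @property
    def n_cells(self) -> int:
        return len(self._data)

    def __len__(self) -> int:
        return self.n_cells

    def __repr__(self) -> str:
        return (
            f"ProfileTable({self.n_cells} cells, "
            f"{len(self.feature_columns)} features, "
            f"{len(self.metadata_columns)} metadata columns)"
        )

    def values(self, features: Sequence[str] | None = None) -> np.ndarray:
        """Feature matrix as a float array, optionally restricted to named features."""
        cols = list(features) if features is not None else self.feature_columns
        missing = [c for c in cols if c not in self._data.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        return self._data[cols].to_numpy(dtype=float)

    def select(self, selector: "PopulationSelector | SelectorLike") -> "ProfileTable":
        return select_population(self, selector)

    def subsample(self, n: int, rng: np.random.Generator) -> "ProfileTable":
        """Uniform random subsample without replacement; identity when n >= n_cells."""
        if n >= self.n_cells:
            return self
        idx = rng.choice(self.n_cells, size=n, replace=False)
        idx.sort()
        return ProfileTable(self._data.iloc[idx], validate=False)

    def write(self, path: str | Path, format: str | None = None) -> None:
        write_profiles(self, path, format=format)


class PopulationSelector:
    """Conjunctive predicate over metadata columns.

    Maps metadata column names to an accepted value or collection of values;
    a row matches when every clause holds.  Bare names are resolved against
    the ``Metadata_`` prefix, so ``{"treatment": "DMSO"}`` and
    ``{"Metadata_treatment": "DMSO"}`` are equivalent.
    """

    def __init__(self, predicate: SelectorLike):
        self.predicate = dict(predicate)

    def resolve(self, table: ProfileTable) -> dict[str, list]:
        """Map clause keys onto the table's metadata columns, normalizing values to lists."""
        resolved: dict[str, list] = {}
        meta = set(table.metadata_columns)
        for key, value in self.predicate.items():
            col = key if key in meta else METADATA_PREFIX + str(key)
            if col not in meta:
                raise KeyError(f"unknown metadata column {key!r}")
            if isinstance(value, (str, bytes)) or not isinstance(value, Iterable):
                value = [value]
            resolved[col] = list(value)
        return resolved

    def mask(self, table: ProfileTable) -> np.ndarray:
        m = np.ones(table.n_cells, dtype=bool)
        for col, accepted in self.resolve(table).items():
            m &= table.data[col].isin(accepted).to_numpy()
        return m

    def __and__(self, other: "PopulationSelector") -> "PopulationSelector":
        merged = dict(self.predicate)
        merged.update(other.predicate)
        return PopulationSelector(merged)

    def __repr__(self) -> str:
        return f"PopulationSelector({self.predicate!r})"


def _as_selector(selector: PopulationSelector | SelectorLike) -> PopulationSelector:
    if isinstance(selector, PopulationSelector):
        return selector
    return PopulationSelector(selector)


def select_population(
    table: ProfileTable, selector: PopulationSelector | SelectorLike
) -> ProfileTable:
    """Rows matching every selector clause; feature schema and row order preserved.

    An empty selector returns the full table.  The result may be empty.
    """
    sel = _as_selector(selector)
    if not sel.predicate:
        return table
    return ProfileTable(table.data[sel.mask(table)], validate=False)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        suffix = path.suffix.lower()
        fmt = {".parquet": "parquet", ".pq": "parquet", ".csv": "csv"}.get(suffix, "")
    if fmt not in ("parquet", "csv"):
        raise ValueError(f"unsupported profile format {format or path.suffix!r}; use parquet or csv")
    return fmt


def load_profiles(
    path: str | Path,
    format: str | None = None,
    missing: str = "error",
) -> ProfileTable:
    """Read a single-cell profile table from Parquet or CSV.

    Parameters
    ----------
    path
        File to read; the format is inferred from the suffix unless given.
    format
        ``"parquet"`` or ``"csv"``.
    missing
        ``"error"`` (default) rejects any missing feature value, naming the
        offending column and row; ``"drop"`` discards rows containing any
        missing feature value and logs the count.  Downstream statistics
        assume complete feature vectors, so silent imputation is never done.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    meta_cols = [c for c in df.columns if str(c).startswith(METADATA_PREFIX)]
    feat_cols = [c for c in df.columns if not str(c).startswith(METADATA_PREFIX)]
    if not meta_cols:
        raise ValueError(f"{path}: no metadata columns (expected at least one {METADATA_PREFIX}* column)")
    if not feat_cols:
        raise ValueError(f"{path}: zero feature columns")
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    if missing == "drop":
        n_before = len(df)
        df = df.dropna(subset=feat_cols).reset_index(drop=True)
        dropped = n_before - len(df)
        if dropped:
            logger.warning("dropped %d of %d cells with missing feature values", dropped, n_before)
    return ProfileTable(df)


def write_profiles(table: ProfileTable, path: str | Path, format: str | None = None) -> None:
    """Write a profile table to Parquet or CSV (format inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "parquet":
        table.data.to_parquet(path, index=False)
    else:
        table.data.to_csv(path, index=False)
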