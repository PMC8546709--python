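"""Readers and writers for abundance tables and sample metadata.

Plain-text tables only (TSV/CSV; the delimiter is inferred from the file
extension and can be overridden).  The canonical in-memory layout is a
pandas DataFrame with samples as rows and taxa as columns; files stored the
other way round are accepted via ``taxa_as_rows=True``.  Blank cells are
read as 0 (absence).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "read_abundance",
    "read_metadata",
    "join_metadata",
    "write_table",
]

log = logging.getLogger(__name__)


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance(
    path,
    delimiter: str | None = None,
    taxa_as_rows: bool = False,
) -> pd.DataFrame:
    """Read a samples x taxa abundance table.

    The first column is treated as the id column.  Blank cells become 0.
    Values must be nonnegative and ids unique; violations raise
    :class:`InvalidInputError` naming the offending cell or ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter(path, delimiter), index_col=0)
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"{path}: file is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InvalidInputError(f"{path}: no data rows/columns")
    if taxa_as_rows:
        df = df.T
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{path}: non-numeric cell ({exc})") from None
    df = df.fillna(0.0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate sample ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate taxon ids {dups}")
    neg = np.argwhere(df.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise InvalidInputError(
            f"{path}: negative value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    return df.rename_axis("sample")


def read_metadata(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table: id column + categorical factor columns.

    Each factor is stored as a categorical whose level order is the order of
    first appearance in the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter(path, delimiter), index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"{path}: file is empty") from None
    if df.shape[1] == 0:
        raise InvalidInputError(f"{path}: metadata has no factor columns")
    for col in df.columns:
        if df[col].isna().all():
            raise InvalidInputError(f"{path}: factor column {col!r} is empty")
        df[col] = pd.Categorical(df[col], categories=pd.unique(df[col].dropna()))
    return df


def join_metadata(abundance: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Align metadata rows to the abundance matrix's samples.

    Samples missing from the metadata are an error; metadata rows without a
    matching sample are dropped with a warning.
    """
    missing = [s for s in abundance.index if s not in metadata.index]
    if missing:
        raise InvalidInputError(f"samples missing from metadata: {missing}")
    extra = [s for s in metadata.index if s not in abundance.index]
    if extra:
        log.warning("dropping %d metadata rows without abundance data: %s", len(extra), extra)
    return metadata.loc[abundance.index]


def write_table(df: pd.DataFrame, path, delimiter: str | None = None) -> Path:
    """Write any erdiv table (abundance, ER coordinates, distances, results)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path, delimiter))
    return path
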