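"""Delimited-table input with complete-case filtering."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = ["read_table"]

logger = logging.getLogger("scoreinv")


def read_table(path, delimiter: str | None = None,
               require_numeric=None) -> pd.DataFrame:
    """Read a rectangular delimited text table (header row, one row per case).

    The delimiter defaults by extension (tab for ``.tsv``, comma otherwise).
    Rows with missing cells are dropped and the count is logged and stored in
    ``df.attrs["n_dropped"]``.  ``require_numeric`` names columns that must
    be numeric (e.g. the item columns).
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ("\t" if path.suffix == ".tsv" else ",")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as e:
        raise ValueError(f"cannot parse {path}: {e}") from e
    if df.shape[1] < 2:
        raise ValueError(f"{path} does not look like a delimited table (sep={sep!r})")
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("read_table: dropped %d incomplete rows of %d from %s",
                    n_dropped, n0, path)
    for c in require_numeric or ():
        if c not in df.columns:
            raise ValueError(f"column {c!r} missing from {path}")
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"column {c!r} in {path} is not numeric")
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return df
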