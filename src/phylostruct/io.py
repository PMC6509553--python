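"""Delimited-text readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_community_matrix", "read_table", "write_table"]


def read_community_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample x species matrix.

    Accepts the wide layout (samples as rows, species as columns, header
    row and index column required) or the long layout with exactly the
    columns ``sample``, ``species``, ``abundance``.
    """
    df = pd.read_csv(path, sep=sep)
    cols_lower = [str(c).strip().lower() for c in df.columns]
    if set(cols_lower) == {"sample", "species", "abundance"}:
        df.columns = cols_lower
        wide = df.pivot_table(
            index="sample", columns="species", values="abundance",
            aggfunc="sum", fill_value=0.0,
        )
        wide.columns.name = None
        wide.index.name = None
        return wide
    wide = pd.read_csv(path, sep=sep, index_col=0)
    if wide.index.duplicated().any() or wide.columns.duplicated().any():
        raise ValueError(f"duplicate sample or species labels in {path}")
    if (wide.values < 0).any():
        raise ValueError(f"negative abundances in {path}")
    return wide.astype(float)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample-indexed table (traits, environment)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate row labels in {path}")
    return df


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
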