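"""Tabular containers and TSV input/output.

Every table in the pipeline is a pandas DataFrame with samples as rows
(index name ``sample_id``) and features (taxa, metabolites, phenotype
columns) as columns.  This module holds the read/write helpers and the
validation routines that enforce the structural invariants the rest of
the package assumes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SAMPLE_INDEX = "sample_id"

#: sentinel header used by the BIOM-style dialect (taxa as rows)
BIOM_SENTINEL = "#OTU ID"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table with samples as rows.

    A BIOM-style orientation (features as rows, first header cell
    ``#OTU ID``) is auto-detected and transposed so that callers always
    receive samples x features.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(BIOM_SENTINEL):
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.T
        df.index.name = SAMPLE_INDEX
        return df
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = SAMPLE_INDEX
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV with a single header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if out.index.name is None:
        out.index.name = SAMPLE_INDEX
    out.to_csv(path, sep="\t")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_abundance(table: pd.DataFrame, *, closed: bool = True, atol: float = 1e-9) -> None:
    """Check relative-abundance invariants.

    Values must lie in [0, 1], taxon ids must be unique, and — unless the
    table has been prevalence-filtered (``closed=False``) — each row must
    sum to 1 within ``atol``.
    """
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate taxon ids: {dupes}")
    vals = table.to_numpy(dtype=float)
    if np.nanmin(vals) < -atol or np.nanmax(vals) > 1 + atol:
        raise ValueError("relative abundances must lie in [0, 1]")
    if closed:
        sums = vals.sum(axis=1)
        bad = np.abs(sums - 1.0) > atol
        if bad.any():
            raise ValueError(
                f"rows do not sum to 1: {table.index[bad].tolist()[:5]} ..."
            )


def validate_phenotypes(table: pd.DataFrame, *, atol: float = 1e-9) -> None:
    """Check phenotype-table invariants.

    Where TOS (uM) and T-AOC (mM) are both present and T-AOC > 0, the OSI
    column must equal their unit-harmonized ratio; concentrations must be
    non-negative.
    """
    for col in ("TOS", "T-AOC"):
        if col in table.columns:
            vals = table[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"negative concentrations in {col}")
    if {"TOS", "T-AOC", "OSI"} <= set(table.columns):
        mask = table["TOS"].notna() & table["T-AOC"].notna() & (table["T-AOC"] > 0)
        if mask.any():
            expected = table.loc[mask, "TOS"] / (table.loc[mask, "T-AOC"] * 1000.0)
            if not np.allclose(table.loc[mask, "OSI"], expected, atol=atol):
                raise ValueError("OSI does not equal TOS / T-AOC in harmonized units")


def align_samples(*tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict tables to their common samples, in a stable order."""
    common: Iterable = tables[0].index
    for t in tables[1:]:
        common = [s for s in common if s in t.index]
    common = list(common)
    if not common:
        raise ValueError("no samples shared between tables")
    return [t.loc[common] for t in tables]
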