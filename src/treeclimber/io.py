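"""Readers and writers for the tabular interchange formats.

Canonical dialect: TSV with a header row (UTF-8); CSV is accepted on read
by sniffing the delimiter.  Readers validate rather than coerce — duplicate
ids, non-numeric cells and missing columns are errors, never silently
repaired.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import CellTable, LeafCountTable
from .tree import Tree, parse_newick

__all__ = [
    "read_counts",
    "read_cells",
    "read_metadata",
    "read_tree",
    "write_table",
    "write_manifest",
]


def _read_delim(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=None, engine="python", **kwargs)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as TSV/CSV ({exc})") from exc


def read_counts(path) -> LeafCountTable:
    """Leaf-level counts: entities in rows (first column), samples in
    columns."""
    df = _read_delim(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate entity labels {dup[:10]}")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric count columns {bad[:10]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in count table")
    return LeafCountTable(counts=df)


def read_cells(path) -> CellTable:
    """Cell table: columns cell_id, leaf_label, sample_id, then one column
    per feature."""
    df = _read_delim(path)
    df.columns = [str(c).strip() for c in df.columns]
    required = ["cell_id", "leaf_label", "sample_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    features = [c for c in df.columns if c not in required]
    if not features:
        raise ValueError(f"{path}: no feature columns found")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids")
    if df[features].isna().any().any():
        raise ValueError(f"{path}: missing feature values")
    cells = df.rename(columns={"leaf_label": "leaf", "sample_id": "sample"})
    cells = cells.set_index("cell_id")
    cells["leaf"] = cells["leaf"].astype(str).str.strip()
    cells["sample"] = cells["sample"].astype(str).str.strip()
    return CellTable(cells=cells)


def read_metadata(path) -> pd.Series:
    """Sample metadata with columns sample_id and group (exactly two
    levels)."""
    df = _read_delim(path)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_ids = df["sample_id"].astype(str).str.strip()
    if sample_ids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    groups = pd.Series(
        df["group"].astype(str).str.strip().to_numpy(),
        index=sample_ids.to_numpy(),
        name="group",
    )
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(
            f"{path}: group column must have exactly 2 levels, found {levels}"
        )
    return groups


def read_tree(path) -> Tree:
    """Rooted tree in Newick format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return parse_newick(path.read_text())


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_manifest(config: dict, path) -> None:
    """Echo the run configuration (plus package version) so a run is
    reproducible from its manifest alone."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, **config}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
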