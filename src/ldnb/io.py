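"""Readers and writers for the pipeline's tabular artifacts.

All tables are TSV by default (comma-separated files are autodetected),
UTF-8, with fixed column orders so runs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .scoring import DNBLandscape
from .ssn import SSNetwork

__all__ = [
    "read_abundance",
    "read_metadata",
    "write_abundance",
    "write_metadata",
    "write_landscape",
    "write_scores",
    "write_edges",
    "write_sif",
    "write_json",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    if path.suffix.lower() == ".csv":
        return ","
    # sniff the header line: comma wins only if no tab present
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("\t" not in header and "," in header) else "\t"


def read_abundance(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Molecule-by-sample intensity table.

    Expects a header row of sample IDs with a ``molecule_id`` first
    column. Duplicate molecule or sample IDs and non-numeric cells are
    rejected with the offending coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={0: str})
    first = df.columns[0]
    if first != "molecule_id":
        raise ValueError(
            f"first column of {path} must be 'molecule_id', found {first!r}"
        )
    dup = df[first][df[first].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate molecule ID(s) in {path}: {sorted(set(dup))}")
    dup_cols = [c for c in df.columns[1:][df.columns[1:].duplicated()]]
    if dup_cols:
        raise ValueError(f"duplicate sample ID(s) in {path}: {dup_cols}")
    df = df.set_index(first)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in {path} at molecule {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
    out = df.astype(float)
    out.index.name = "molecule_id"
    return out


def read_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Sample metadata: ``sample_id`` and ``group`` columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata {path} must have a {col!r} column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ID(s) in {path}: {sorted(set(dup))}")
    return df.set_index("sample_id")


def write_abundance(abundance: pd.DataFrame, path: str | Path) -> None:
    abundance.rename_axis("molecule_id").to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def write_landscape(landscape: DNBLandscape, path: str | Path) -> None:
    landscape.table().to_csv(path, sep="\t", index=False)


def write_scores(score_table: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "group", "global_dnb_score"]
    score_table[cols].to_csv(path, sep="\t", index=False)


def write_edges(ssn: SSNetwork, path: str | Path) -> None:
    ssn.edge_table().to_csv(path, sep="\t", index=False)


def write_sif(ssn: SSNetwork, path: str | Path) -> None:
    """Simple interaction format: `a spcc b` per significant edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in ssn.edges():
            fh.write(f"{e.molecule_a}\tspcc\t{e.molecule_b}\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(payload: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
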