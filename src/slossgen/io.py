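"""Readers and writers for the pipeline's plain-text formats.

Formats: FASTA for alignments (island id in the header as
``>spec0001|island=I03`` or via a separate two-column CSV map), newick
for trees (branch lengths mandatory), CSV for island metadata and
haplotype-by-island occurrence matrices, JSON for results.  CSVs are
UTF-8, comma-separated, with a mandatory header row; an em-dash or empty
cell is read as missing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import PhyloTree

__all__ = [
    "read_islands",
    "read_occurrence",
    "read_tree",
    "read_alignment",
    "write_alignment",
    "write_occurrence",
    "write_diversity",
    "write_json",
    "sha256_of",
]

ISLAND_REQUIRED = ["AREA"]
ISLAND_KNOWN = ["Island", "LON", "LAT", "AREA", "COA", "ISD", "ISW", "POP", "FRE"]
MISSING_TOKENS = ["—", "-", "NA", ""]


def read_islands(path: str | Path) -> pd.DataFrame:
    """Read an island metadata CSV; the index is the ID (or Island) column."""
    df = pd.read_csv(path, na_values=MISSING_TOKENS, thousands=",")
    index_col = "ID" if "ID" in df.columns else "Island"
    if index_col not in df.columns:
        raise ValueError(f"{path}: island table needs an 'ID' or 'Island' column")
    df = df.set_index(index_col)
    df.index = df.index.astype(str)
    missing = [c for c in ISLAND_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: island table lacks columns: {missing}")
    area = pd.to_numeric(df["AREA"], errors="coerce")
    if area.isna().any() or (area <= 0).any():
        bad = df.index[area.isna() | (area <= 0)].tolist()
        raise ValueError(f"{path}: non-positive or missing AREA for {bad}")
    df["AREA"] = area
    return df


def read_occurrence(path: str | Path) -> pd.DataFrame:
    """Read a haplotype-by-island count matrix (haplotypes as rows)."""
    df = pd.read_csv(path, index_col=0, na_values=MISSING_TOKENS)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    vals = df.to_numpy()
    if pd.isna(vals).any():
        raise ValueError(f"{path}: occurrence matrix has missing cells")
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{path}: occurrence counts must be nonnegative integers")
    return df.astype(int)


def reconcile(occurrence: pd.DataFrame, islands: pd.DataFrame) -> None:
    """Fail loudly when occurrence columns reference unknown islands."""
    unknown = [c for c in occurrence.columns if c not in islands.index]
    if unknown:
        raise ValueError(
            f"occurrence references island(s) absent from the island table: {unknown}"
        )


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree.from_file(path)


def read_alignment(
    path: str | Path, island_map_path: str | Path | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Read a specimen FASTA; island ids come from headers or a map CSV.

    Headers of the form ``spec0001|island=I03`` carry the island inline;
    otherwise ``island_map_path`` must name a CSV with columns
    ``specimen,island``.
    """
    sequences: dict[str, str] = {}
    island_map: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "|island=" in name:
            spec_id, island = name.split("|island=", 1)
            island_map[spec_id] = island
        else:
            spec_id = name
        sequences[spec_id] = str(rec.seq)
    if island_map_path is not None:
        m = pd.read_csv(island_map_path)
        if not {"specimen", "island"} <= set(m.columns):
            raise ValueError("island map CSV needs 'specimen' and 'island' columns")
        island_map.update(dict(zip(m["specimen"].astype(str), m["island"].astype(str))))
    unmapped = [s for s in sequences if s not in island_map]
    if unmapped:
        raise ValueError(f"specimens without island assignment: {unmapped[:5]}")
    return sequences, island_map


def write_alignment(
    path: str | Path, sequences: Mapping[str, str], island_map: Mapping[str, str]
) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{sid}|island={island_map[sid]}", description="")
        for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_occurrence(path: str | Path, occurrence: pd.DataFrame) -> None:
    out = occurrence.copy()
    out.index.name = "haplotype"
    out.to_csv(path)


def write_diversity(path: str | Path, table: pd.DataFrame, pretty: bool = False) -> None:
    """Write the per-island diversity table.

    Machine-readable output leaves undefined Hd empty; ``pretty=True``
    writes the em-dash convention used in printed tables.
    """
    out = table.copy()
    if pretty and "Hd" in out.columns:
        out["Hd"] = out["Hd"].map(lambda v: "—" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
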