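"""Readers and writers for the on-disk formats.

Coordinate conventions are fixed package-wide: probe positions are 1-based
points; binding-site intervals are 0-based half-open (native BED). All
conversion between the two happens in the intersection layer, never here.
Readers validate strictly and raise :class:`FormatError` (with a line
number where one exists) instead of coercing malformed input; every writer
round-trips through its reader. Paths ending in ``.gz`` are read and
written through gzip transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED binding sites

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED4+ intervals into a binding-site table.

    Returns a DataFrame with columns chrom, start, end, site_id (0-based
    half-open). A missing name column yields synthesized ids
    ``chrom:start-end``. An empty file is an empty set, not an error.
    """
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            site_id = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, site_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "site_id"])
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise FormatError(f"{path}: duplicate site_id {dup!r}")
    return df


def write_bed(sites: pd.DataFrame, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for chrom, start, end, site_id in sites[["chrom", "start", "end", "site_id"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{site_id}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT collection: set name, description, tab-separated members.

    Duplicate members within a set are deduplicated (order kept) with a
    logged warning; a duplicate set name is a format error.
    """
    collection: dict[str, tuple[str, list[str]]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns (name, description, members)")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "%s:%d: set %r contains %d duplicate member(s); deduplicated",
                    path, lineno, name, len(members) - len(deduped),
                )
            collection[name] = (desc, deduped)
    return collection


def write_gmt(collection: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# beta matrix

def read_beta_matrix(path: str | Path, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix (TSV, 'NA' = missing).

    Values outside [0, 1] and duplicated probe rows are format errors.
    When a manifest is supplied, probes absent from it are dropped with a
    logged count.
    """
    with _open(path) as fh:
        df = pd.read_csv(
            fh, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
            float_precision="round_trip",
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated probe row {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-numeric cell in beta matrix") from None
    bad = np.argwhere((values < 0.0) | (values > 1.0))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: beta value {values[i, j]} outside [0, 1] "
            f"at probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    df = pd.DataFrame(values, index=df.index, columns=df.columns)
    df.index.name = "probe_id"
    if manifest is not None:
        keep = df.index.isin(manifest["probe_id"])
        if (~keep).any():
            logger.info("%s: dropped %d probe(s) absent from manifest", path, int((~keep).sum()))
            df = df.loc[keep]
    return df


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        beta.to_csv(fh, sep="\t", na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# small tables: manifest, sample sheet, TSS annotation, IHC sheet

def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_open(path))
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id in manifest")
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: manifest positions are 1-based, must be >= 1")
    if "strand" in df.columns:
        bad = ~df["strand"].isin(VALID_STRANDS) & df["strand"].notna()
        if bad.any():
            raise FormatError(f"{path}: invalid strand {df.loc[bad, 'strand'].iloc[0]!r}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(_open(path, "wt"), index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_open(path))
    if not {"sample_id", "group"}.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in sample sheet")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(_open(path, "wt"), index=False)


def read_tss(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_open(path), sep="\t")
    required = {"gene_id", "gene_name", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id in TSS table")
    if not df["strand"].isin(VALID_STRANDS).all():
        bad = df.loc[~df["strand"].isin(VALID_STRANDS), "strand"].iloc[0]
        raise FormatError(f"{path}: strand must be '+' or '-', got {bad!r}")
    if (df["tss"] < 1).any():
        raise FormatError(f"{path}: TSS coordinates are 1-based, must be >= 1")
    return df


def write_tss(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(_open(path, "wt"), sep="\t", index=False)


def read_ihc_sheet(path: str | Path) -> pd.DataFrame:
    """Read a per-core IHC sheet.

    Requires sample_id and group plus either raw ``percent_positive``
    (0-100) or a pre-binned ``category`` (0-4) alongside ``intensity``;
    range validation happens in the scoring module.
    """
    df = pd.read_csv(_open(path))
    if not {"sample_id", "group"}.issubset(df.columns):
        raise FormatError(f"{path}: IHC sheet needs columns sample_id, group")
    if "intensity" not in df.columns:
        raise FormatError(f"{path}: IHC sheet needs an intensity column")
    if "percent_positive" not in df.columns and "category" not in df.columns:
        raise FormatError(f"{path}: IHC sheet needs percent_positive or category")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
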