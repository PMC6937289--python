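"""Readers and writers for the pipeline's plain-text schemas.

Field data travel as comma-separated CSV (UTF-8, ``.`` decimal); array data
as tab-separated TSV following the GenePix results convention.  Every file
written by the package carries a ``#``-prefixed metadata header (tool
version, parameters, seed, SHA-1 of inputs); all readers skip such comment
lines, so outputs round-trip.
"""

from __future__ import annotations

import hashlib
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "SchemaError",
    "read_internode_csv",
    "write_table",
    "read_array_tsv",
    "read_go_map",
    "read_qpcr_csv",
    "file_sha1",
]

INTERNODE_REQUIRED = [
    "variety",
    "treatment",
    "replicate",
    "culm",
    "internode",
    "length_cm",
    "diameter_mm",
    "wall_mm",
]
INTERNODE_OPTIONAL = [
    "fresh_g",
    "dry_mg",
    "dist_tip_cm",
    "fresh_above_g",
    "break_N",
    "deflect_cm",
    "elastic_F_N",
    "span_cm",
]

#: GenePix results columns mapped onto the canonical array schema.
GENEPIX_COLUMNS = {
    "ID": "probe_id",
    "Name": "probe_id",
    "F532 Mean": "cy3",
    "F635 Mean": "cy5",
    "Flags": "flag",
}


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def file_sha1(path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(
    df: pd.DataFrame,
    path,
    *,
    metadata: Optional[Mapping[str, object]] = None,
    sep: str = ",",
    index: bool = False,
) -> None:
    """Write a table with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# lodgekit output\n")
        fh.write(f"# written: {datetime.now(timezone.utc).isoformat(timespec='seconds')}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep=sep, index=index)


def _read(path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, comment="#", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_internode_csv(path, *, strict: bool = True) -> pd.DataFrame:
    """Read and validate an internode measurement table.

    Mandatory columns: variety, treatment, replicate, culm, internode,
    length_cm, diameter_mm, wall_mm.  Optional measurement columns are kept
    when present; unknown extra columns are ignored.  Row-level invariant
    violations are collected and reported with 1-based data line numbers;
    ``strict=True`` raises on any violation, ``strict=False`` drops the
    offending rows.
    """
    df = _read(path, ",")
    missing = [c for c in INTERNODE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    keep = INTERNODE_REQUIRED + [c for c in INTERNODE_OPTIONAL if c in df.columns]
    df = df[keep].copy()
    if "span_cm" not in df.columns:
        df["span_cm"] = 5.0

    for col in keep:
        if col not in ("variety", "treatment"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

    problems = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        msgs = []
        if pd.isna(row.length_cm) or row.length_cm <= 0:
            msgs.append("length_cm must be positive")
        if pd.isna(row.diameter_mm) or row.diameter_mm <= 0:
            msgs.append("diameter_mm must be positive")
        elif pd.isna(row.wall_mm) or not 0 < row.wall_mm <= row.diameter_mm / 2:
            msgs.append("wall_mm outside (0, diameter_mm/2]")
        if pd.isna(row.internode) or not 1 <= row.internode <= 5:
            msgs.append("internode index outside 1..5")
        if (
            hasattr(row, "break_N")
            and not pd.isna(row.break_N)
            and not pd.isna(row.length_cm)
            and row.length_cm < row.span_cm
        ):
            msgs.append("break_N present although length_cm < span_cm")
        if msgs:
            problems.append((pos, "; ".join(msgs)))

    if problems:
        detail = "\n".join(f"  line {ln}: {msg}" for ln, msg in problems)
        if strict:
            raise SchemaError(f"{path}: {len(problems)} invalid row(s):\n{detail}")
        bad = {ln - 1 for ln, _ in problems}
        df = df.drop(df.index[list(bad)]).reset_index(drop=True)
        if df.empty:
            raise SchemaError(f"{path}: all rows invalid:\n{detail}")
    return df


def read_array_tsv(path) -> pd.DataFrame:
    """Read a two-channel replicate TSV (canonical or GenePix-style header).

    Canonical columns: probe_id, cy3, cy5, flag.  GenePix results columns
    ("F532 Mean", "F635 Mean", "Flags", "ID") are mapped onto them; numeric
    GenePix flags < 0 become ``bad``, others ``ok``.  Duplicate probe ids
    are an error.
    """
    df = _read(path, "\t")
    if "probe_id" not in df.columns:
        renames = {k: v for k, v in GENEPIX_COLUMNS.items() if k in df.columns}
        if "probe_id" not in renames.values():
            raise SchemaError(f"{path}: no probe_id (or GenePix ID) column")
        df = df.rename(columns=renames)
        df = df.loc[:, ~df.columns.duplicated()]
    for col in ("cy3", "cy5"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing channel column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any() or (df[col] < 0).any():
            raise SchemaError(f"{path}: non-numeric or negative {col} intensities")
    if "flag" in df.columns and pd.api.types.is_numeric_dtype(df["flag"]):
        df["flag"] = pd.Series(["bad" if f < 0 else "ok" for f in df["flag"]], index=df.index)
    if "flag" not in df.columns:
        df["flag"] = "ok"
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise SchemaError(f"{path}: duplicate probe id(s), e.g. {df['probe_id'][dup].iloc[0]!r}")
    return df[["probe_id", "cy3", "cy5", "flag"]]


def read_go_map(path) -> pd.DataFrame:
    """Read a two-column gene->GO-term TSV (one pair per line)."""
    df = _read(path, "\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns gene_id<TAB>term")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "term"]
    if df.duplicated().any():
        df = df.drop_duplicates()
    return df.reset_index(drop=True)


def read_qpcr_csv(path) -> pd.DataFrame:
    """Read a tidy qPCR Ct table with columns gene, treatment, ct."""
    df = _read(path, ",")
    missing = {"gene", "treatment", "ct"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if df["ct"].isna().any():
        raise SchemaError(f"{path}: non-numeric Ct values")
    return df
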