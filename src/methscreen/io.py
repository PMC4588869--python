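"""File formats and unit conventions.

Internally methylation is a proportion in [0, 1]; every user-facing
table carries percent (0-100) with explicitly unit-suffixed column
names (``*_pct``), so a mixed-unit table cannot be written.  Genomic
coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_probe_table",
    "write_methylation_matrix",
    "read_methylation_matrix",
    "sha256_of",
]

log = logging.getLogger(__name__)

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a 3-6 column BED file (0-based half-open).

    Malformed lines raise with their line number; zero-width records
    (start == end, the hallmark of accidentally 1-based input) are
    rejected; unsorted input is sorted on read with a logged notice.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if not 3 <= len(parts) <= 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 3-6 tab-separated fields, got {len(parts)}"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end == start:
                raise ValueError(
                    f"{path}:{lineno}: zero-width interval (start == end); "
                    "BED is 0-based half-open — is this 1-based input?"
                )
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            if len(parts) >= 6 and parts[5] not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            rows.append([parts[0], start, end] + parts[3:])
    df = pd.DataFrame(rows, columns=_BED_COLS[: ncols or 3])
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    sorted_df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        log.info("%s: input not coordinate-sorted; sorted on read", path)
    return sorted_df.reset_index(drop=True)


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write regions (chrom/start/end[/name/score/strand]) as BED."""
    cols = [c for c in _BED_COLS if c in regions.columns]
    if not {"chrom", "start", "end"}.issubset(cols):
        raise ValueError("regions need at least chrom/start/end")
    regions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets: one tab-separated line per set, name, description,
    then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_probe_table(path) -> pd.DataFrame:
    """Probe TSV: BED-style coordinates plus per-sample log2-ratio columns."""
    df = pd.read_csv(path, sep="\t")
    need = {"probe_id", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"probe table must have columns {sorted(need)}")
    if not np.isfinite(df.select_dtypes("number").to_numpy()).all():
        raise ValueError("probe table contains non-finite values")
    return df


def write_methylation_matrix(
    regions: pd.DataFrame, methylation_prop: pd.DataFrame, path
) -> None:
    """Write a windows x samples methylation table in percent.

    Sample columns are suffixed ``_pct`` so the unit is part of the
    header; input values must be proportions in [0, 1].
    """
    vals = methylation_prop.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("methylation must be proportions in [0, 1]")
    out = regions[["chrom", "start", "end"]].copy()
    for c in methylation_prop.columns:
        out[f"{c}_pct"] = 100.0 * methylation_prop[c].to_numpy(dtype=float)
    if "uninformative" in regions.columns:
        out["uninformative"] = regions["uninformative"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_methylation_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_methylation_matrix`: back to proportions."""
    df = pd.read_csv(path, sep="\t")
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    if not pct_cols:
        raise ValueError("no *_pct sample columns found; wrong table?")
    meta_cols = [c for c in df.columns if not c.endswith("_pct")]
    meth = df[pct_cols] / 100.0
    meth.columns = [c[: -len("_pct")] for c in pct_cols]
    return df[meta_cols], meth


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
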