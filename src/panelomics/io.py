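"""Table readers/writers shared by all stages.

TSV is the canonical dialect (comma-separated files are accepted by
sniffing the header line); UTF-8 throughout; empty cells and "NA" are
missing. Row and column identifiers are opaque case-sensitive strings.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .docking import DockedCompound
from .errors import PanelomicsError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_two_column_map",
    "read_docking_table",
]

_NA_VALUES = ["", "NA"]


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise PanelomicsError(f"{path}: no data lines")


def read_matrix(path) -> pd.DataFrame:
    """Read a features x cell-lines (or compounds x cell-lines) matrix.

    First column holds row identifiers, header row holds column
    identifiers. Duplicate identifiers raise; non-numeric cells raise
    with the offending (row, column) coordinates.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sniff_sep(path), comment="#", index_col=0,
        na_values=_NA_VALUES, keep_default_na=False, dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise PanelomicsError(f"{path}: duplicate row id(s) {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise PanelomicsError(f"{path}: duplicate column id(s) {dupes}")
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise PanelomicsError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a matrix in the dialect :func:`read_matrix` reads back."""
    df.to_csv(path, sep=sep, na_rep="")


def read_two_column_map(path) -> dict[str, str]:
    """Read a two-column id -> label file (e.g. agent->class, line->tissue)."""
    path = Path(path)
    sep = _sniff_sep(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header_skipped = False
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if not header_skipped:
                header_skipped = True
                continue
            key, value = row[0], row[1]
            if key in out:
                raise PanelomicsError(f"{path}: duplicate id {key!r}")
            out[key] = value
    return out


def read_docking_table(path) -> list[DockedCompound]:
    """Read a docking score table (one :class:`DockedCompound` per row).

    Expected headers: name, lbe_mean, lbe_sd, pki_mean, pki_sd,
    pki_unit, site, pharmacophore (semicolon-separated residues).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str)
    required = {"name", "lbe_mean", "pki_mean"}
    missing = required - set(df.columns)
    if missing:
        raise PanelomicsError(f"{path}: missing column(s) {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        pharm = rec.get("pharmacophore") or ""
        rows.append(
            DockedCompound(
                name=rec["name"],
                lbe_mean=float(rec["lbe_mean"]),
                lbe_sd=float(rec.get("lbe_sd") or 0.0),
                pki_mean=float(rec["pki_mean"]),
                pki_sd=float(rec.get("pki_sd") or 0.0),
                pki_unit=rec.get("pki_unit") or "uM",
                site_label=rec.get("site") or "",
                pharmacophore=tuple(
                    p.strip() for p in pharm.split(";") if p.strip()
                ),
            )
        )
    return rows
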