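"""Reading and writing marker panels and genotype tables.

Canonical dialect: tab-separated, UTF-8, header row required, "NA" for
missing values.  Comma-separated files are accepted on read (the delimiter is
sniffed).  Genotype calls are encoded 0/1/2/NA for HOM_P1/HET/HOM_P2/missing.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import DataError
from .markers import (
    META_COLUMNS,
    MISSING,
    GenotypeTable,
    MarkerDef,
    MarkerPanel,
)

PathLike = Union[str, Path]

_CALL_FROM_STR = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
_STR_FROM_CALL = {0: "0", 1: "1", 2: "2", MISSING: "NA"}


def _sniff_sep(path: PathLike) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"  # single-column file


def _read_raw(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=_sniff_sep(path), dtype=str, keep_default_na=False
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise DataError(f"{path}: cannot parse table: {exc}") from exc


def read_marker_panel(path: PathLike) -> MarkerPanel:
    """Read a marker map table (columns marker_id, chromosome, position_cM)."""
    df = _read_raw(path)
    required = {"marker_id", "chromosome", "position_cM"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    seen = set()
    markers = []
    for i, row in df.iterrows():
        mid = row["marker_id"]
        if mid in seen:
            raise DataError(f"{path}: duplicate marker_id {mid!r}")
        seen.add(mid)
        try:
            pos = float(row["position_cM"])
        except ValueError:
            raise DataError(
                f"{path}: row {i + 2}: non-numeric position_cM "
                f"{row['position_cM']!r}"
            ) from None
        markers.append(MarkerDef(mid, row["chromosome"], pos))
    return MarkerPanel(markers)


def write_marker_panel(panel: MarkerPanel, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker_id", "chromosome", "position_cM"])
        for m in panel.markers:
            w.writerow([m.marker_id, m.chromosome, _fmt_num(m.position_cM)])


def _fmt_num(x: float) -> str:
    return format(x, "g")


def read_genotype_table(path: PathLike, panel: MarkerPanel) -> GenotypeTable:
    """Read a genotype table against a panel.

    The file carries the metadata columns first, then one column per marker
    with values in {0, 1, 2, NA}.  Marker columns may be a subset of the
    panel (absent markers become MISSING); columns naming markers not in the
    panel are rejected.
    """
    df = _read_raw(path)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise DataError(f"{path}: missing metadata columns {missing_meta}")
    marker_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in marker_cols if c not in panel.marker_ids]
    if unknown:
        raise DataError(f"{path}: columns for unknown markers {unknown}")

    n = len(df)
    calls = np.full((n, panel.n_markers), MISSING, dtype=np.int8)
    for col in marker_cols:
        j = panel.index_of(col)
        for i, v in enumerate(df[col]):
            try:
                calls[i, j] = _CALL_FROM_STR[v]
            except KeyError:
                raise DataError(
                    f"{path}: row {i + 2}, column {col!r}: invalid genotype "
                    f"value {v!r} (expected 0/1/2/NA)"
                ) from None

    meta = df[list(META_COLUMNS)].copy()
    temp = []
    for i, v in enumerate(meta["temperature_C"]):
        if v in ("NA", ""):
            temp.append(np.nan)
        else:
            try:
                temp.append(float(v))
            except ValueError:
                raise DataError(
                    f"{path}: row {i + 2}: non-numeric temperature_C {v!r}"
                ) from None
    meta["temperature_C"] = temp
    return GenotypeTable(panel, meta, calls)


def write_genotype_table(table: GenotypeTable, path: PathLike) -> None:
    """Write a genotype table in the canonical TSV dialect.

    read_genotype_table(write_genotype_table(t)) reproduces ``t`` exactly,
    and rewriting the reread table is byte-identical.
    """
    meta = table.meta
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(META_COLUMNS) + table.panel.marker_ids)
        for i in range(table.n_individuals):
            row = []
            for c in META_COLUMNS:
                v = meta.iloc[i][c]
                if c == "temperature_C":
                    v = "NA" if pd.isna(v) else _fmt_num(float(v))
                row.append(str(v))
            row.extend(_STR_FROM_CALL[int(x)] for x in table.calls[i])
            w.writerow(row)
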