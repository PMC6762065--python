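"""Readers and writers for the pipeline's tab-separated text formats.

Everything is plain TSV with a header row and the explicit missing-value
token "NA"; gene sets use the standard GMT dialect (set name, description,
then tab-separated members, one set per line). Round-tripping any writer
through its reader is lossless on canonical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable
import warnings

import pandas as pd

from .errors import InvalidMatrixError, ParseError
from .types import BehavioralRecord, GeneSetCollection, OmicsMatrix

NA_TOKEN = "NA"

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_behavior",
    "write_behavior",
]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members...

    Duplicate members on a line are deduplicated with a warning; a line with
    fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_matrix(path: str | Path, meta_path: str | Path, modality: str) -> OmicsMatrix:
    """Load a feature x sample TSV plus its sample metadata table.

    The matrix file has feature ids in the first column; the metadata file
    has columns ``sample_id, strain, tissue, group, batch``. Validation
    (metadata coverage, integer non-negative counts for count modalities,
    unique feature ids) happens in the OmicsMatrix constructor.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    meta = pd.read_csv(meta_path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "sample_id" not in meta.columns:
        raise ParseError(f"{meta_path}: metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    return OmicsMatrix(values, meta, modality)


def write_matrix(matrix: OmicsMatrix, path: str | Path, meta_path: str | Path) -> None:
    vals = matrix.values.copy()
    vals.index.name = "feature_id"
    vals.to_csv(path, sep="\t", na_rep=NA_TOKEN)
    meta = matrix.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", na_rep=NA_TOKEN)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV result table with NA handling."""
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)


def read_behavior(path: str | Path) -> list[BehavioralRecord]:
    """Read a behavioral TSV: mouse_id, strain, group, t_iz_no_target, t_iz_target[, weight_day*].

    Weight columns (any column starting with ``weight_day``) are optional
    and collected in day order into each record's weight series.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    required = ["mouse_id", "strain", "group", "t_iz_no_target", "t_iz_target"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing behavioral columns {missing}")
    weight_cols = sorted(
        (c for c in df.columns if c.startswith("weight_day")),
        key=lambda c: int(c.removeprefix("weight_day")),
    )
    records = []
    for row in df.itertuples(index=False):
        weights = None
        if weight_cols:
            series = [getattr(row, c) for c in weight_cols]
            if not any(pd.isna(w) for w in series):
                weights = [float(w) for w in series]
        records.append(
            BehavioralRecord(
                str(row.mouse_id),
                str(row.strain),
                str(row.group),
                float(row.t_iz_no_target),
                float(row.t_iz_target),
                weights,
            )
        )
    return records


def write_behavior(records: Iterable[BehavioralRecord], path: str | Path) -> None:
    records = list(records)
    n_days = max((len(r.weights) for r in records if r.weights), default=0)
    rows = []
    for r in records:
        row = {
            "mouse_id": r.mouse_id,
            "strain": r.strain,
            "group": r.group,
            "t_iz_no_target": r.t_iz_no_target,
            "t_iz_target": r.t_iz_target,
        }
        for d in range(n_days):
            w = r.weights[d] if r.weights and d < len(r.weights) else None
            row[f"weight_day{d + 1}"] = w
        rows.append(row)
    write_table(pd.DataFrame(rows), path)
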