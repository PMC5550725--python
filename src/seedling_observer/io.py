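"""Dataset and report I/O.

Datasets travel as one flat UTF-8 CSV with a mandatory header in schema
order: ``sample_id, trial_id, e1..e8, p1_d0..p10_d0, ..., p1_d9..p10_d9,
g1_d3, g2_d3, g1_d6, g2_d6, g1_d9, g2_d9, g3, g4``.  Values are written
with 12 significant digits, so a write/read round trip is value-exact at
that precision.  Block membership is recovered from column prefixes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import SCHEMA_COLUMNS, SeedlingDataset

__all__ = ["SchemaError", "read_dataset", "write_dataset", "write_json"]

MEASUREMENT_COLUMNS = tuple(c for c in SCHEMA_COLUMNS if c not in ("sample_id",))


class SchemaError(ValueError):
    """The file does not conform to the dataset schema."""


def write_dataset(dataset: SeedlingDataset, path: str | Path) -> Path:
    """Write a dataset CSV (and its ground truth, if any, alongside)."""
    path = Path(path)
    dataset.frame.to_csv(path, index=False, float_format="%.12g")
    if dataset.ground_truth is not None:
        write_json(dataset.ground_truth, path.with_suffix(".truth.json"))
    return path


def read_dataset(path: str | Path) -> SeedlingDataset:
    """Read and validate a dataset CSV.

    Raises :class:`SchemaError` naming the offending column/row on a
    missing or misordered header, a duplicate sample id, or a
    non-numeric/missing measurement cell.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    header = list(frame.columns)
    missing = [c for c in SCHEMA_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if header != list(SCHEMA_COLUMNS):
        raise SchemaError(
            f"{path}: header does not match schema order; expected "
            f"{list(SCHEMA_COLUMNS)[:4]}..., got {header[:4]}..."
        )
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample_id value(s) {dupes}")
    for col in MEASUREMENT_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if bad.size:
            # +2: header line plus 1-based row numbering
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"file row {bad[0] + 2}"
            )
        frame[col] = values
    truth_path = path.with_suffix(".truth.json")
    truth = None
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return SeedlingDataset(frame=frame, ground_truth=truth)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
    return path
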