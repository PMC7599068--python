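"""Reading and writing of the pipeline's tabular and array inputs.

The central exchange format is the *cell table*: one row per detected
nucleus centre, in micrometres, with specimen and group annotations.
Tables travel as tab-delimited text; synthetic ground truth travels as a
JSON sidecar next to the table it describes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: Required columns of a cell table, in canonical order.
CELL_TABLE_COLUMNS = [
    "larva_id",
    "genotype",
    "side",
    "x_um",
    "y_um",
    "z_um",
    "marker",
    "label",
]

_COORD_COLUMNS = ["x_um", "y_um", "z_um"]
_SIDES = {"left", "right"}


class SchemaError(ValueError):
    """A table does not conform to the cell-table schema."""


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table, returning it with canonical column order.

    Checks: all required columns present, finite coordinates, non-empty
    genotype/side fields, side restricted to left/right.

    Raises
    ------
    SchemaError
        Naming the first offending column.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s): {missing}")
    coords = df[_COORD_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = [c for c in _COORD_COLUMNS if not np.all(np.isfinite(df[c].astype(float)))]
        raise SchemaError(f"non-finite coordinates in column(s): {bad}")
    if df["genotype"].isna().any() or (df["genotype"].astype(str) == "").any():
        raise SchemaError("empty genotype values")
    sides = set(df["side"].astype(str).unique())
    if not sides <= _SIDES:
        raise SchemaError(f"side must be one of {_SIDES}, got {sides - _SIDES}")
    return df[CELL_TABLE_COLUMNS].copy()


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(df).to_csv(path, sep="\t", index=False)


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
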