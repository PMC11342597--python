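"""Tabular and metadata I/O shared by all modules.

CSV is the interchange format for every tidy table in the pipeline; numeric
columns round-trip at full precision (Python's shortest-repr float printing
is lossless). JSON carries run metadata (config echo + seeds).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "write_metadata", "read_metadata"]


def write_table(path, table: pd.DataFrame) -> None:
    """Write a tidy table as CSV (lossless for float64 columns)."""
    table.to_csv(path, index=False)


def read_table(path, require_columns=None) -> pd.DataFrame:
    """Read a CSV table; malformed rows raise with the offending line number."""
    try:
        table = pd.read_csv(path, on_bad_lines="error")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed table {path}: {err}") from err
    if require_columns is not None:
        missing = set(require_columns) - set(table.columns)
        if missing:
            raise ValueError(f"table {path} lacks columns {sorted(missing)}")
    return table


def write_metadata(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
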