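"""Tabular readers/writers (TSV, CSV, JSON) with full-precision round trips."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["write_table", "read_table"]

_DIALECTS = {"TSV": "\t", "CSV": ","}


def _records_to_frame(rows: Sequence[Mapping]) -> pd.DataFrame:
    rows = list(rows)
    if rows:
        keys = tuple(rows[0].keys())
        for r in rows:
            if tuple(r.keys()) != keys:
                raise ValueError("heterogeneous records: differing keys")
    return pd.DataFrame.from_records(rows)


def write_table(rows, path, dialect: str = "TSV", columns: Iterable[str] | None = None) -> None:
    """Write homogeneous records (or a DataFrame) to TSV/CSV/JSON.

    Floats are serialized with ``repr`` so the read/write round trip is
    bit-exact. An empty record list with explicit ``columns`` yields a
    header-only file.
    """
    dialect = dialect.upper()
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = _records_to_frame(rows)
        if frame.empty and columns is not None:
            frame = pd.DataFrame(columns=list(columns))
    path = Path(path)
    if dialect == "JSON":
        payload = frame.to_dict(orient="records")
        path.write_text(json.dumps({"columns": list(frame.columns), "records": payload},
                                   indent=1, default=str) + "\n")
    elif dialect in _DIALECTS:
        # %.17g round-trips any IEEE double exactly
        frame.to_csv(path, sep=_DIALECTS[dialect], index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a table written by :func:`write_table`; dialect inferred from the
    suffix when not given."""
    path = Path(path)
    if dialect is None:
        dialect = {".tsv": "TSV", ".csv": "CSV", ".json": "JSON"}.get(path.suffix.lower(), "TSV")
    dialect = dialect.upper()
    if dialect == "JSON":
        obj = json.loads(path.read_text())
        return pd.DataFrame.from_records(obj["records"], columns=obj["columns"])
    if dialect in _DIALECTS:
        return pd.read_csv(path, sep=_DIALECTS[dialect], float_precision="round_trip")
    raise ValueError(f"unknown dialect {dialect!r}")
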