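"""Case-table CSV I/O and deterministic report writers.

Case CSV format: header row of node names verbatim (spaces allowed, RFC 4180
quoting), one row per observation day, cells are state labels or empty for
missing. Reports are TSV or versioned JSON with deterministic field order;
displayed numbers follow the reporting style of the accuracy tables (three
decimals for p-values, one decimal for percentages) while JSON retains full
precision.
"""

from __future__ import annotations

import csv
import json
from typing import Any

import pandas as pd

from .core import NetworkSpec

REPORT_SCHEMA_VERSION = 1


def read_case_table(path, spec: NetworkSpec | None = None) -> pd.DataFrame:
    """Read a case CSV; empty cells become missing (NaN).

    With a network given, unknown columns and unknown state labels are
    rejected with the offending column / row named.
    """
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed case CSV {path}: {exc}") from exc
    table = table.replace({"": None})
    if spec is not None:
        for column in table.columns:
            if column not in spec:
                raise ValueError(
                    f"case table column {column!r} is not a node of the network"
                )
            valid = set(spec.node(column).states)
            col = table[column].dropna()
            bad = col[~col.isin(valid)]
            if not bad.empty:
                raise ValueError(
                    f"unknown state {bad.iloc[0]!r} in column {column!r}, "
                    f"row {int(bad.index[0]) + 2} of {path}"  # +2: header + 1-based
                )
    return table


def write_case_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def _round_floats(obj: Any, digits: int = 12) -> Any:
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def write_report(results: dict, format: str, path, meta: dict | None = None) -> None:
    """Write an analysis report deterministically (same input, same bytes).

    ``results`` is a flat-ish mapping from the validation / sensitivity /
    scenario commands. JSON output is schema-versioned; TSV flattens to
    key<TAB>value rows with nested mappings dotted.
    """
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    if meta:
        payload["meta"] = meta
    payload["results"] = _round_floats(results)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        rows: list[tuple[str, Any]] = []

        def flatten(prefix: str, obj: Any) -> None:
            if isinstance(obj, dict):
                for k in obj:
                    flatten(f"{prefix}.{k}" if prefix else str(k), obj[k])
            elif isinstance(obj, (list, tuple)):
                rows.append((prefix, ";".join(str(_round_floats(v)) for v in obj)))
            else:
                rows.append((prefix, obj))

        flatten("", payload["results"])
        with open(path, "w") as fh:
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def display_percent(value: float) -> str:
    """One-decimal percent, e.g. 0.7955 -> '79.6'."""
    return f"{100 * value:.1f}"


def display_p(value: float) -> str:
    """Three-decimal p-value, e.g. 0.02135 -> '0.021'."""
    return f"{value:.3f}"
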