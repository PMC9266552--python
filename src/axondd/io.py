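"""Cohort-table I/O and JSON serialization helpers.

The interchange format for per-axon measurements is a CSV with the exact
header ``animal_id,group,apnea,diameter_um``; diameters are in μm (the unit
suffix in the header is mandatory — no unit autodetection).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortFormatError",
    "REQUIRED_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_json",
    "config_hash",
]

REQUIRED_COLUMNS = ("animal_id", "group", "apnea", "diameter_um")

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class CohortFormatError(ValueError):
    """Malformed cohort CSV; the message lists offending line numbers."""


def _parse_apnea(value, line: int, problems: list[str]) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    problems.append(f"line {line}: unparseable apnea flag {value!r}")
    return False


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Malformed rows (non-positive or non-numeric diameters, bad apnea flags)
    are reported with their 1-based file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")
    problems: list[str] = []
    # header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    diameters = pd.to_numeric(df["diameter_um"], errors="coerce")
    for i, (d, line) in enumerate(zip(diameters, lines)):
        if not np.isfinite(d):
            problems.append(
                f"line {line}: non-numeric diameter {df['diameter_um'].iloc[i]!r}"
            )
        elif d <= 0:
            problems.append(f"line {line}: non-positive diameter {d!r}")
    apnea = [
        _parse_apnea(v, line, problems) for v, line in zip(df["apnea"], lines)
    ]
    if problems:
        raise CohortFormatError(f"{path}: " + "; ".join(problems))
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["apnea"] = apnea
    out["diameter_um"] = diameters.astype(float)
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["apnea"] = out["apnea"].astype(bool)
    out.to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n"
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (provenance block)."""
    canonical = json.dumps(_jsonify(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
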