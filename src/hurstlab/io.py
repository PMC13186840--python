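"""Long-format CSV interchange, result writing, and run configuration.

The single interchange format is a long CSV with header
``subject,group,day,trial,variable,stride,value``; stride indices must be
contiguous within each trial. Results (estimates, grids, power tables) are
written as tidy one-row-per-record CSV or JSON with floats at 10 significant
digits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fgn import COHORT_COLUMNS
from .types import StrideSeries

__all__ = [
    "read_series_csv",
    "series_to_frame",
    "write_results",
    "read_results",
    "RunConfig",
    "RESULTS_JSON_SCHEMA",
    "validate_results_json",
]


def read_series_csv(
    path,
    variable: Optional[str] = None,
    group: Optional[str] = None,
    subject: Optional[str] = None,
) -> List[StrideSeries]:
    """Read a long-format cohort CSV into validated StrideSeries.

    Malformed rows are reported with their 1-based data line numbers; a gap
    in the stride index is reported with the offending trial's labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()] if df["value"].dtype == object else df.index[values.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"non-numeric values at file lines {lines}")
    df = df.assign(value=values)

    for col, want in [("variable", variable), ("group", group), ("subject", subject)]:
        if want is not None:
            df = df[df[col] == want]
    if df.empty:
        return []

    out: List[StrideSeries] = []
    keys = ["subject", "group", "day", "trial", "variable"]
    for (subj, grp, day, trial, var), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("stride", kind="mergesort")
        strides = sub["stride"].to_numpy()
        expected = np.arange(strides[0], strides[0] + strides.size)
        if not np.array_equal(strides, expected):
            raise ValueError(
                f"non-contiguous stride index for subject={subj!r} day={day} "
                f"trial={trial} variable={var!r}"
            )
        out.append(StrideSeries(
            values=sub["value"].to_numpy(), subject=str(subj), group=str(grp),
            day=int(day), trial=int(trial), variable=str(var),
        ))
    return out


def series_to_frame(series_list: Sequence[StrideSeries]) -> pd.DataFrame:
    """Assemble StrideSeries back into the long interchange format."""
    parts = []
    for s in series_list:
        parts.append(pd.DataFrame({
            "subject": s.subject, "group": s.group, "day": s.day,
            "trial": s.trial, "variable": s.variable,
            "stride": np.arange(1, len(s) + 1), "value": s.values,
        }))
    if not parts:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.concat(parts, ignore_index=True)[COHORT_COLUMNS]


def _round_sig(x: float, sig: int = 10) -> float:
    return float(f"{x:.{sig}g}")


def _to_records(objects) -> List[Mapping[str, Any]]:
    if isinstance(objects, pd.DataFrame):
        return objects.to_dict(orient="records")
    records = []
    for obj in objects:
        if dataclasses.is_dataclass(obj):
            rec = dataclasses.asdict(obj)
        elif isinstance(obj, Mapping):
            rec = dict(obj)
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
        records.append(rec)
    return records


def write_results(objects, path, format: str = "csv") -> None:
    """Write records as tidy CSV or JSON (floats at 10 significant digits)."""
    records = _to_records(objects)
    fmt = format.lower()
    if fmt == "csv":
        frame = pd.DataFrame.from_records(records)
        if frame.empty and isinstance(objects, pd.DataFrame):
            frame = objects
        frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    elif fmt == "json":
        clean = [
            {k: _round_sig(v) if isinstance(v, float) else v for k, v in rec.items()}
            for rec in records
        ]
        with open(path, "w") as fh:
            json.dump(clean, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path, format: str = "csv"):
    if format.lower() == "csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return json.load(fh)


RESULTS_JSON_SCHEMA = {
    "type": "array",
    "items": {
        "type": "object",
        "propertyTypes": (str, int, float, bool, type(None)),
    },
}


def validate_results_json(payload) -> bool:
    """Check a parsed results payload against the shipped schema."""
    if not isinstance(payload, list):
        raise ValueError("results JSON must be an array of records")
    allowed = RESULTS_JSON_SCHEMA["items"]["propertyTypes"]
    for rec in payload:
        if not isinstance(rec, dict):
            raise ValueError("each record must be an object")
        for key, val in rec.items():
            if not isinstance(key, str) or not isinstance(val, allowed):
                raise ValueError(f"invalid entry {key!r}: {val!r}")
    return True


@dataclass
class RunConfig:
    """Serializable run configuration; identical config => identical outputs."""

    seed: int = 0
    reps: int = 500
    method: str = "hkp"
    delta_h: float = 0.08
    n_trials: int = 1
    series_length: int = 100
    n_grid: Sequence[int] = field(default_factory=lambda: list(range(10, 81, 2)))
    stride_counts: Sequence[int] = field(default_factory=lambda: [50, 100, 150])
    trials_used: Sequence[int] = field(default_factory=lambda: list(range(1, 10)))
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
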