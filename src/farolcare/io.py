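"""CSV input/output for visit series and indicator tables.

Visit series CSV dialect: header ``date,count``, ISO-8601 dates, one row
per day, consecutive days.  Counts may carry thousands separators, which
are stripped on load.  Indicator CSV dialect: header
``category,name,national,instance,comprehensive_index[,weight]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .beliefs import VisitSeries
from .errors import DataValidationError
from .payoff import IndicatorRecord

__all__ = [
    "load_visit_csv",
    "write_visit_csv",
    "load_indicator_csv",
    "write_indicator_csv",
    "write_table",
]


def _strip_commas(value) -> str:
    return str(value).replace(",", "").strip()


def load_visit_csv(path) -> VisitSeries:
    """Load a ``date,count`` CSV into a validated :class:`VisitSeries`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = {"date", "count"} - set(frame.columns)
    if missing:
        raise DataValidationError(
            f"{path}: missing column(s) {sorted(missing)}; expected header date,count"
        )
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(frame["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: unparseable date ({exc})") from exc
    try:
        counts = np.array([int(float(_strip_commas(v))) for v in frame["count"]])
    except ValueError as exc:
        raise DataValidationError(f"{path}: unparseable count ({exc})") from exc
    return VisitSeries(dates, counts)


def write_visit_csv(series: VisitSeries, path) -> None:
    frame = series.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def load_indicator_csv(path) -> list[IndicatorRecord]:
    """Load indicator records; numeric fields may carry thousands separators."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"category", "name", "national", "instance"}
    missing = required - set(frame.columns)
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        def num(col, optional=False):
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                if optional:
                    return None
                raise DataValidationError(f"{path} line {i + 2}: missing {col}")
            try:
                return float(_strip_commas(raw))
            except ValueError as exc:
                raise DataValidationError(
                    f"{path} line {i + 2}: unparseable {col} ({raw!r})"
                ) from exc

        records.append(
            IndicatorRecord(
                name=str(row["name"]),
                category=str(row["category"]).strip(),
                national_value=num("national"),
                instance_value=num("instance"),
                comprehensive_index=num("comprehensive_index", optional=True),
                weight=num("weight", optional=True),
            )
        )
    return records


def write_indicator_csv(records, path) -> None:
    pd.DataFrame(
        {
            "category": [r.category for r in records],
            "name": [r.name for r in records],
            "national": [r.national_value for r in records],
            "instance": [r.instance_value for r in records],
            "comprehensive_index": [r.comprehensive_index for r in records],
            "weight": [r.weight for r in records],
        }
    ).to_csv(path, index=False)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a report table as CSV (dates rendered ISO, no index column)."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
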