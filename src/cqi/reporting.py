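"""Measure reports: machine-readable output of an evaluation.

A report echoes the indicator's metadata and effective parameter values
next to the population counts and score, plus a summary of the repository
it was computed over.  Reports are deterministic for fixed inputs; an
evaluation timestamp is added only on request so that repeated runs stay
byte-identical.  The dashboard aggregation turns many reports into one
summary table (one row per indicator and period) for external plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import pandas as pd

from .cdr import TimeInterval, format_cell
from .engine import MeasureResult, POP_FIELDS
from .model import Indicator

__all__ = ["MeasureReport", "build_report", "validate_report_dict",
           "dashboard", "ReportFormatError"]

REPORT_SCHEMA_VERSION = "1.0"


class ReportFormatError(ValueError):
    pass


@dataclass
class MeasureReport:
    """Wraps one :class:`~cqi.engine.MeasureResult` with its provenance."""

    indicator_name: str
    indicator_version: str
    status: str
    measure_type: str
    parameters: dict[str, str]
    counts: dict[str, int]
    score: Optional[float]
    score_exact: Optional[str]          # "numerator/denominator" rational
    observation_total: Optional[float]
    repository_rows: dict[str, int]
    populations: dict[str, list[str]]
    evaluation_time: Optional[str] = None
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        out = {
            "schema_version": self.schema_version,
            "indicator": {"name": self.indicator_name,
                          "version": self.indicator_version,
                          "status": self.status,
                          "measure_type": self.measure_type},
            "parameters": self.parameters,
            "counts": self.counts,
            "score": self.score,
            "score_exact": self.score_exact,
            "observation_total": self.observation_total,
            "repository_rows": self.repository_rows,
            "populations": self.populations,
        }
        if self.evaluation_time is not None:
            out["evaluation_time"] = self.evaluation_time
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_csv(self) -> str:
        row = {"indicator": self.indicator_name,
               "version": self.indicator_version,
               "measure_type": self.measure_type,
               **{k: str(v) for k, v in self.parameters.items()},
               **self.counts,
               "score": "" if self.score is None else repr(self.score),
               "observation_total": ("" if self.observation_total is None
                                     else self.observation_total)}
        return pd.DataFrame([row]).to_csv(index=False, lineterminator="\n")


def _fmt_param(value) -> str:
    if isinstance(value, TimeInterval):
        return (f"{value.low.isoformat()}..{value.high.isoformat()}")
    return format_cell(value)


def build_report(ind: Indicator, result: MeasureResult,
                 params: dict[str, object],
                 repository_rows: dict[str, int],
                 stamp: bool = False) -> MeasureReport:
    score = result.score
    return MeasureReport(
        indicator_name=ind.metadata.indicator_name,
        indicator_version=ind.metadata.version,
        status=ind.metadata.status,
        measure_type=result.measure_type,
        parameters={k: _fmt_param(v) for k, v in params.items()},
        counts=result.counts(),
        score=None if score is None else float(score),
        score_exact=None if score is None
        else f"{score.numerator}/{score.denominator}",
        observation_total=(result.observation_total
                           if result.measure_type == "count" else None),
        repository_rows=repository_rows,
        populations={f: sorted(getattr(result, f)) for f in POP_FIELDS},
        evaluation_time=(datetime.now().isoformat(timespec="seconds")
                        if stamp else None),
    )


_REQUIRED_KEYS = {
    "schema_version": str, "indicator": dict, "parameters": dict,
    "counts": dict, "repository_rows": dict, "populations": dict,
}
_INDICATOR_KEYS = {"name": str, "version": str, "status": str,
                   "measure_type": str}


def validate_report_dict(data: dict) -> None:
    """Structural check of a report JSON object against the shipped report
    schema; raises :class:`ReportFormatError` on the first violation."""
    if not isinstance(data, dict):
        raise ReportFormatError("report must be a JSON object")
    for key, typ in _REQUIRED_KEYS.items():
        if key not in data:
            raise ReportFormatError(f"report lacks required key {key!r}")
        if not isinstance(data[key], typ):
            raise ReportFormatError(f"report key {key!r} must be "
                                    f"{typ.__name__}")
    for key, typ in _INDICATOR_KEYS.items():
        v = data["indicator"].get(key)
        if not isinstance(v, typ):
            raise ReportFormatError(f"indicator.{key} must be {typ.__name__}")
    if data["indicator"]["measure_type"] not in ("proportion", "count"):
        raise ReportFormatError("indicator.measure_type must be "
                                "'proportion' or 'count'")
    for k, v in data["counts"].items():
        if not isinstance(v, int) or v < 0:
            raise ReportFormatError(f"counts[{k!r}] must be a non-negative "
                                    "integer")
    score = data.get("score")
    if score is not None and not (isinstance(score, (int, float))
                                  and 0 <= score <= 1):
        raise ReportFormatError("score must be null or a number in [0, 1]")
    for k, v in data["populations"].items():
        if not isinstance(v, list):
            raise ReportFormatError(f"populations[{k!r}] must be a list")
        if len(v) != data["counts"].get(k, len(v)):
            raise ReportFormatError(
                f"populations[{k!r}] disagrees with counts[{k!r}]")


def dashboard(reports: list[dict], warn=None) -> pd.DataFrame:
    """Aggregate report objects into a summary table.

    One row per (indicator, period), sorted by indicator name then period;
    duplicates keep the last report seen, with a warning through ``warn``.
    """
    if not reports:
        raise ReportFormatError("dashboard needs at least one report")
    rows: dict[tuple, dict] = {}
    for data in reports:
        validate_report_dict(data)
        period = data["parameters"].get("MeasurementPeriod", "")
        key = (data["indicator"]["name"], period)
        if key in rows and warn is not None:
            warn(f"duplicate report for {key[0]!r} period {period!r}; "
                 "keeping the last one")
        counts = data["counts"]
        rows[key] = {
            "indicator": key[0],
            "version": data["indicator"]["version"],
            "period": period,
            "measure_type": data["indicator"]["measure_type"],
            "initial_population": counts.get("initial_population", 0),
            "denominator": counts.get("denominator", 0),
            "exclusions": counts.get("denominator_exclusions", 0),
            "effective_denominator": counts.get("effective_denominator", 0),
            "numerator": counts.get("numerator", 0),
            "score": data.get("score"),
            "observation_total": data.get("observation_total"),
        }
    df = pd.DataFrame(sorted(rows.values(),
                             key=lambda r: (r["indicator"], r["period"])))
    return df
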