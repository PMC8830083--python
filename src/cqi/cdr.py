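"""Simplified archetype-relational clinical data repository.

Each (archetype, template) pair that an indicator retrieves becomes one
table whose columns are the bound openEHR element paths plus ``patient_id``
and ``entry_time`` — a deliberately flat stand-in for a full
archetype-relational mapping, keeping the engine agnostic to the storage
behind the ``retrieve`` contract.

Fixture tables are plain CSV.  Cells are typed by their lexical shape:
``system|code`` is a coded value, ``value|unit`` (numeric first part) a
quantity, ISO-8601 text a timestamp, ``true``/``false`` a boolean, bare
numbers are numeric, anything else is text, and the empty cell is null.
Timestamps are timezone-naive at second precision.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

import pandas as pd

from .model import Indicator, list_required_archetypes
from .terminology import ResolvedValueSet, code_matches, CodeSystemRegistry

__all__ = [
    "Coded", "Quantity", "TimeInterval", "EntryRecord",
    "TableSchema", "CdrSchema", "Repository",
    "schema_from_indicator", "load_fixture", "table_filename",
    "parse_cell", "format_cell",
    "SchemaMismatchError", "CdrTypeError", "UnknownTableError",
]


@dataclass(frozen=True)
class Coded:
    """A coded value as stored in the repository: (system, code)."""

    system: str
    code: str

    def __str__(self) -> str:
        return f"{self.system}|{self.code}"


@dataclass(frozen=True)
class Quantity:
    """A magnitude with a unit, e.g. 138 mmHg."""

    value: float
    unit: str

    def __str__(self) -> str:
        return f"{format_number(self.value)}|{self.unit}"


@dataclass(frozen=True)
class TimeInterval:
    """A time interval with explicit bound inclusivity (default
    closed-open)."""

    low: Optional[datetime]
    high: Optional[datetime]
    low_closed: bool = True
    high_closed: bool = False

    def contains(self, point: datetime) -> Optional[bool]:
        if point is None or self.low is None or self.high is None:
            return None
        if self.low_closed:
            if point < self.low:
                return False
        elif point <= self.low:
            return False
        if self.high_closed:
            if point > self.high:
                return False
        elif point >= self.high:
            return False
        return True

    def contains_interval(self, other: "TimeInterval") -> Optional[bool]:
        if None in (self.low, self.high, other.low, other.high):
            return None
        lo_ok = (other.low > self.low or
                 (other.low == self.low and (self.low_closed or
                                             not other.low_closed)))
        hi_ok = (other.high < self.high or
                 (other.high == self.high and (self.high_closed or
                                               not other.high_closed)))
        return lo_ok and hi_ok


@dataclass
class EntryRecord:
    """One patient-linked entry of an archetype table."""

    patient_id: str
    archetype_id: str
    entry_time: datetime
    values: dict[str, object]
    template_id: Optional[str] = None
    uid: Optional[tuple] = field(default=None, compare=False)


@dataclass
class TableSchema:
    archetype_id: str
    template_id: Optional[str]
    paths: list[str]


@dataclass
class CdrSchema:
    """Declared table layout: one table per (archetype, template) pair."""

    tables: dict[tuple[str, Optional[str]], TableSchema] = field(
        default_factory=dict)

    def require(self, archetype_id: str,
                template_id: Optional[str]) -> TableSchema:
        key = (archetype_id, template_id)
        if key not in self.tables:
            raise UnknownTableError(
                f"no table declared for archetype {archetype_id!r}"
                + (f" / template {template_id!r}" if template_id else ""))
        return self.tables[key]


class SchemaMismatchError(ValueError):
    pass


class CdrTypeError(TypeError):
    pass


class UnknownTableError(KeyError):
    pass


def schema_from_indicator(ind: Indicator) -> CdrSchema:
    """Derive the repository schema an indicator needs: one table per
    required binding, columns being the union of bound element paths of
    all aliases sharing the same (archetype, template)."""
    required = list_required_archetypes(ind)   # also enforces validity
    schema = CdrSchema()
    for ab in ind.archetype_bindings:
        key = (ab.archetype_id, ab.template_id)
        if key not in required:
            continue
        table = schema.tables.setdefault(
            key, TableSchema(ab.archetype_id, ab.template_id, []))
        for e in ab.elements:
            if e.element_path not in table.paths:
                table.paths.append(e.element_path)
    return schema


_FILENAME_SAFE = re.compile(r"[^A-Za-z0-9._\-]")


def table_filename(archetype_id: str, template_id: Optional[str]) -> str:
    name = archetype_id
    if template_id:
        name += f"__{template_id}"
    return _FILENAME_SAFE.sub("_", name) + ".csv"


# -- cell typing ------------------------------------------------------------

_ISO_DT_RE = re.compile(r"^\d{4}-\d{2}-\d{2}([T ]\d{2}:\d{2}:\d{2})?$")
_NUM_RE = re.compile(r"^-?\d+(\.\d+)?$")


def parse_cell(text: str) -> object:
    """Type a CSV cell by its lexical shape (see module docstring)."""
    if text == "":
        return None
    if "|" in text:
        first, rest = text.split("|", 1)
        if _NUM_RE.match(first):
            return Quantity(value=float(first), unit=rest)
        return Coded(system=first, code=rest)
    if text == "true":
        return True
    if text == "false":
        return False
    if _ISO_DT_RE.match(text):
        return datetime.fromisoformat(text)
    if _NUM_RE.match(text):
        return int(text) if "." not in text else float(text)
    return text


def format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def format_cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (Coded, Quantity)):
        return str(value)
    if isinstance(value, datetime):
        return value.isoformat(timespec="seconds")
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


_KIND = {Coded: "coded", Quantity: "quantity", datetime: "timestamp",
         bool: "boolean", int: "number", float: "number", str: "text"}


def _kind(value: object) -> str:
    return _KIND[type(value)]


class Repository:
    """In-memory repository of typed, patient-linked entries."""

    def __init__(self, schema: CdrSchema):
        self.schema = schema
        self._tables: dict[tuple, list[EntryRecord]] = {
            key: [] for key in schema.tables}
        self._by_patient: dict[tuple, dict[str, list[EntryRecord]]] = {
            key: {} for key in schema.tables}

    # -- loading ----------------------------------------------------------
    def add(self, archetype_id: str, template_id: Optional[str],
            record: EntryRecord) -> None:
        key = (archetype_id, template_id)
        self.schema.require(archetype_id, template_id)
        rows = self._tables[key]
        record.uid = (key, len(rows))
        rows.append(record)
        self._by_patient[key].setdefault(record.patient_id, []).append(record)

    def row_counts(self) -> dict[str, int]:
        return {table_filename(*key): len(rows)
                for key, rows in sorted(self._tables.items(),
                                        key=lambda kv: str(kv[0]))}

    def patients(self) -> list[str]:
        out: set[str] = set()
        for idx in self._by_patient.values():
            out.update(idx.keys())
        return sorted(out)

    # -- retrieval --------------------------------------------------------
    def rows_for_patient(self, archetype_id: str,
                         template_id: Optional[str],
                         patient_id: str) -> list[EntryRecord]:
        """Entries of one patient in load order."""
        self.schema.require(archetype_id, template_id)
        return list(self._by_patient[(archetype_id, template_id)]
                    .get(patient_id, []))

    def retrieve(self, archetype_id: str, template_id: Optional[str] = None,
                 term_filter: Optional[tuple[str, ResolvedValueSet]] = None,
                 time_window: Optional[TimeInterval] = None,
                 patient_id: Optional[str] = None,
                 registry: Optional[CodeSystemRegistry] = None
                 ) -> list[EntryRecord]:
        """Entries matching every supplied filter.

        ``term_filter`` is (element path, value set): the entry's coded
        value at that path must be a member.  ``time_window`` tests the
        entry timestamp.  Result order is stable: (patient_id, entry_time,
        load order).
        """
        self.schema.require(archetype_id, template_id)
        key = (archetype_id, template_id)
        if patient_id is not None:
            rows: Iterable[EntryRecord] = self._by_patient[key].get(
                patient_id, [])
        else:
            rows = self._tables[key]
        out = []
        for rec in rows:
            if term_filter is not None:
                path, vs = term_filter
                v = rec.values.get(path)
                if not isinstance(v, Coded):
                    continue
                if not code_matches((v.system, v.code), vs, registry):
                    continue
            if time_window is not None:
                if time_window.contains(rec.entry_time) is not True:
                    continue
            out.append(rec)
        out.sort(key=lambda r: (r.patient_id, r.entry_time, r.uid[1]))
        return out


def load_fixture(path: str, schema: CdrSchema) -> Repository:
    """Load a directory of per-table CSV files into a repository.

    A table whose file is absent loads empty.  A declared column missing
    from a present file raises :class:`SchemaMismatchError`; a cell whose
    type conflicts with the rest of its column, or an unparseable
    timestamp, raises :class:`CdrTypeError` with its row number.
    """
    repo = Repository(schema)
    for key, table in schema.tables.items():
        fname = os.path.join(path, table_filename(*key))
        if not os.path.exists(fname):
            continue
        df = pd.read_csv(fname, dtype=str, keep_default_na=False)
        missing = [c for c in ["patient_id", "entry_time"] + table.paths
                   if c not in df.columns]
        if missing:
            raise SchemaMismatchError(
                f"{fname}: missing column(s) {', '.join(missing)}")
        col_kind: dict[str, str] = {}
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rowd = dict(zip(df.columns, row))
            pid = rowd["patient_id"].strip()
            if not pid:
                raise CdrTypeError(f"{fname}: row {i}: empty patient_id")
            et = parse_cell(rowd["entry_time"])
            if not isinstance(et, datetime):
                raise CdrTypeError(
                    f"{fname}: row {i}: entry_time "
                    f"{rowd['entry_time']!r} is not an ISO timestamp")
            values: dict[str, object] = {}
            for p in table.paths:
                v = parse_cell(rowd[p])
                values[p] = v
                if v is not None:
                    k = _kind(v)
                    prev = col_kind.setdefault(p, k)
                    if prev != k:
                        raise CdrTypeError(
                            f"{fname}: row {i}: column {p!r} mixes "
                            f"{prev} and {k} values")
            repo.add(table.archetype_id, table.template_id,
                     EntryRecord(patient_id=pid,
                                 archetype_id=table.archetype_id,
                                 template_id=table.template_id,
                                 entry_time=et, values=values))
    return repo


def write_fixture(path: str, schema: CdrSchema,
                  rows: dict[tuple, list[EntryRecord]]) -> dict[str, int]:
    """Write per-table CSV files in the fixture dialect; returns the row
    count per written file.  Tables are always written (possibly with a
    header only) so an empty cohort still loads."""
    os.makedirs(path, exist_ok=True)
    counts = {}
    for key, table in schema.tables.items():
        fname = table_filename(*key)
        cols = ["patient_id", "entry_time"] + table.paths
        recs = rows.get(key, [])
        data = [[r.patient_id, format_cell(r.entry_time)]
                + [format_cell(r.values.get(p)) for p in table.paths]
                for r in recs]
        df = pd.DataFrame(data, columns=cols)
        df.to_csv(os.path.join(path, fname), index=False,
                  lineterminator="\n")
        counts[fname] = len(recs)
    return counts
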