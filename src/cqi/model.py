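"""Object model for clinical quality indicator artifacts.

An indicator artifact couples four declaration blocks — management metadata,
terminology bindings, archetype bindings and expression logic — into one
computable unit.  The expression logic is a small CQL-style language whose
queries retrieve openEHR entries through locally aliased archetype bindings
and constrain coded values through locally coded terminology bindings.

The classes here are the in-memory representation shared by the parser, the
serializers and the evaluation engine.  Structural and referential
constraints are checked by :func:`validate_indicator`, which reports coded
issues rather than raising, so authoring tools can surface every problem at
once.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterator, Optional, Union

__all__ = [
    "Status", "MetadataBlock", "ParameterDecl", "ElementBinding",
    "ArchetypeBinding", "TermRef", "TermBinding", "DefineStatement",
    "Indicator", "SourceSpan",
    "Expr", "Literal", "NameRef", "DefineRef", "Retrieve", "Projection",
    "Filter", "Exists", "Count", "Not", "FirstByTime", "LastByTime",
    "Binary", "During", "IntervalLit", "AgeInYearsAt", "SetOp", "TimeShift",
    "Start", "End", "EntryTimeRef",
    "Issue", "ValidationReport", "validate_indicator",
    "list_required_archetypes", "topological_define_order",
    "UnvalidatedIndicatorError", "CyclicDefinesError",
    "POPULATION_NAMES", "AT_CODE_RE",
]

AT_CODE_RE = re.compile(r"^at\d{4}(?:-at\d{4})?$")

#: Reserved, case-insensitive define names that the engine maps onto the
#: standard populations of a proportion (or count) measure.
POPULATION_NAMES = (
    "initialpopulation",
    "denominator",
    "denominatorexclusions",
    "numerator",
    "numeratorexclusions",
    "denominatorexceptions",
    "measureobservation",
)


class Status(str, Enum):
    """Lifecycle state of an indicator artifact."""

    DRAFT = "DRAFT"
    REVIEWING = "REVIEWING"
    PUBLISHED = "PUBLISHED"
    DEPRECATED = "DEPRECATED"


@dataclass(frozen=True)
class SourceSpan:
    """Position of a token or node in the indicator source text (1-based)."""

    line: int
    column: int
    length: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}, column {self.column}"


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------
# Node equality deliberately ignores source spans so that round-tripped
# artifacts compare field-identical.

def _span_field():
    return field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class Literal:
    """Constant: Integer, Decimal, String, DateTime, Boolean or Null."""

    value: object
    value_type: str
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class NameRef:
    """Bare identifier: a parameter, or an element code of the enclosing
    query source (classified during validation, resolved at evaluation)."""

    name: str
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class EntryTimeRef:
    """The entry timestamp of the current query row."""

    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class DefineRef:
    """Reference to an earlier define statement, written ``"Name"``."""

    name: str
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class TermRef:
    """A single term: (code system, code), e.g. (ICD-10, I10)."""

    system: str
    code: str
    system_uri: Optional[str] = None
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Retrieve:
    """``[ALIAS]`` or ``[ALIAS : TERM]`` — all entries of the bound
    archetype for the current patient, optionally constrained so that at
    least one coded element value belongs to the term's value set.  TERM is
    a terminology-binding local code or an inline ``SYS::[CODE]`` term."""

    alias: str
    term: Union[str, TermRef, None] = None
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Projection:
    """``source.E0001`` — element value(s) of an entry or entry list."""

    source: "Expr"
    element_code: str
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Filter:
    """``source where condition`` (CQL query with a where clause)."""

    source: "Expr"
    condition: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Exists:
    operand: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Count:
    operand: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Not:
    operand: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class FirstByTime:
    """``First(source sort by key)`` — earliest entry; key is an element
    code or the entry timestamp; ties resolved by load order."""

    source: "Expr"
    key: str = "entry_time"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class LastByTime:
    """``Last(source sort by key)`` — latest entry; ties by load order."""

    source: "Expr"
    key: str = "entry_time"
    span: Optional[SourceSpan] = _span_field()


BINARY_OPS = ("=", "!=", "<", "<=", ">", ">=", "and", "or", "+", "-", "*", "/")


@dataclass(frozen=True)
class Binary:
    op: str
    left: "Expr"
    right: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class During:
    """``point during interval`` or ``interval during interval``."""

    operand: "Expr"
    interval: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class IntervalLit:
    """``Interval[low, high)`` — bracket style fixes bound inclusivity."""

    low: "Expr"
    high: "Expr"
    low_closed: bool = True
    high_closed: bool = False
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class AgeInYearsAt:
    """Completed calendar years between a birth timestamp and a point."""

    birth: "Expr"
    at: "Expr"
    span: Optional[SourceSpan] = _span_field()


SET_OPS = ("union", "intersect", "except")


@dataclass(frozen=True)
class SetOp:
    op: str
    left: "Expr"
    right: "Expr"
    span: Optional[SourceSpan] = _span_field()


TIME_UNITS = ("hours", "days", "months", "years")


@dataclass(frozen=True)
class TimeShift:
    """``base + 6 months`` / ``base - 24 hours`` — calendar-aware shift
    (month and year arithmetic clamps the day of month)."""

    base: "Expr"
    amount: int
    unit: str
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class Start:
    """``start of interval``."""

    operand: "Expr"
    span: Optional[SourceSpan] = _span_field()


@dataclass(frozen=True)
class End:
    """``end of interval``."""

    operand: "Expr"
    span: Optional[SourceSpan] = _span_field()


Expr = Union[
    Literal, NameRef, EntryTimeRef, DefineRef, TermRef, Retrieve, Projection,
    Filter, Exists, Count, Not, FirstByTime, LastByTime, Binary, During,
    IntervalLit, AgeInYearsAt, SetOp, TimeShift, Start, End,
]


def children(expr: Expr) -> Iterator[Expr]:
    """Yield the direct sub-expressions of a node."""
    for f in dataclasses.fields(expr):
        if f.name == "span":
            continue
        v = getattr(expr, f.name)
        if isinstance(v, _NODE_TYPES):
            yield v


_NODE_TYPES = (
    Literal, NameRef, EntryTimeRef, DefineRef, TermRef, Retrieve, Projection,
    Filter, Exists, Count, Not, FirstByTime, LastByTime, Binary, During,
    IntervalLit, AgeInYearsAt, SetOp, TimeShift, Start, End,
)


def walk(expr: Expr) -> Iterator[Expr]:
    """Depth-first pre-order traversal of an expression tree."""
    yield expr
    for c in children(expr):
        yield from walk(c)


# ---------------------------------------------------------------------------
# Declaration blocks
# ---------------------------------------------------------------------------

@dataclass
class MetadataBlock:
    indicator_name: str
    version: str = "0.1.0"
    language: str = "en"
    translations: list[str] = field(default_factory=list)
    description: str = ""
    status: str = Status.DRAFT.value
    author: str = ""
    time: Optional[datetime] = None
    email: str = ""


@dataclass
class ParameterDecl:
    name: str
    param_type: str  # Interval<DateTime>, DateTime, Integer, Decimal, String, Code
    default_value: Optional[Expr] = None


PARAM_TYPES = ("Interval<DateTime>", "DateTime", "Integer", "Decimal", "String", "Code")


@dataclass
class ElementBinding:
    """Local element code -> openEHR path within the bound archetype."""

    element_code: str
    element_path: str


@dataclass
class ArchetypeBinding:
    """Local alias -> archetype (optionally placed in a template slot).

    ``slot_path`` is the archetype's path inside the template; the empty
    string means the archetype is not slotted.
    """

    alias: str
    archetype_id: str
    template_id: Optional[str] = None
    slot_path: str = ""
    elements: list[ElementBinding] = field(default_factory=list)
    predicates: list[Expr] = field(default_factory=list)

    def element_path(self, code: str) -> Optional[str]:
        for e in self.elements:
            if e.element_code == code:
                return e.element_path
        return None


@dataclass
class TermBinding:
    """Local code -> one or more terms, with disjunctive ("any of")
    membership semantics.  Archetype-internal at-codes carry the archetype
    they come from in ``source_archetype``."""

    local_code: str
    refs: list[TermRef]
    source_archetype: Optional[str] = None


@dataclass
class DefineStatement:
    name: str
    body: Expr


@dataclass
class Indicator:
    metadata: MetadataBlock
    parameters: list[ParameterDecl] = field(default_factory=list)
    term_bindings: list[TermBinding] = field(default_factory=list)
    archetype_bindings: list[ArchetypeBinding] = field(default_factory=list)
    defines: list[DefineStatement] = field(default_factory=list)

    @property
    def measure_type(self) -> str:
        """``"count"`` when a MeasureObservation define is present,
        otherwise ``"proportion"`` (rate-based)."""
        if self.find_define("MeasureObservation") is not None:
            return "count"
        return "proportion"

    def find_define(self, name: str) -> Optional[DefineStatement]:
        low = name.lower()
        for d in self.defines:
            if d.name.lower() == low:
                return d
        return None

    def binding(self, alias: str) -> Optional[ArchetypeBinding]:
        for b in self.archetype_bindings:
            if b.alias == alias:
                return b
        return None

    def term_binding(self, local_code: str) -> Optional[TermBinding]:
        for t in self.term_bindings:
            if t.local_code == local_code:
                return t
        return None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    code: str
    message: str
    location: str = ""
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:
        where = f" [{self.location}]" if self.location else ""
        return f"{self.severity.upper()} {self.code}: {self.message}{where}"


class ValidationReport(list):
    """List of :class:`Issue`; an indicator is valid iff no error issues."""

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self if i.severity == "error"]


class UnvalidatedIndicatorError(ValueError):
    """Raised by operations whose precondition is a valid indicator."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(
            "indicator failed validation: "
            + "; ".join(str(i) for i in report.errors)
        )


class CyclicDefinesError(ValueError):
    pass


def _source_alias(ind: Indicator, expr: Expr, memo: dict) -> Optional[str]:
    """Statically determine which archetype binding a query expression draws
    its rows from, or None when it cannot be decided (e.g. a union of two
    different sources)."""
    if isinstance(expr, Retrieve):
        return expr.alias
    if isinstance(expr, (Filter, FirstByTime, LastByTime)):
        return _source_alias(ind, expr.source, memo)
    if isinstance(expr, SetOp):
        a = _source_alias(ind, expr.left, memo)
        b = _source_alias(ind, expr.right, memo)
        return a if a == b else None
    if isinstance(expr, DefineRef):
        key = expr.name.lower()
        if key in memo:
            return memo[key]
        memo[key] = None  # cycle guard
        d = ind.find_define(expr.name)
        if d is not None:
            memo[key] = _source_alias(ind, d.body, memo)
        return memo[key]
    return None


def validate_indicator(ind: Indicator) -> ValidationReport:
    """Check every structural and referential invariant of an artifact.

    Returns a report of coded issues; the indicator is valid iff the report
    contains no error-severity issue.  Pure and idempotent.
    """
    report = ValidationReport()
    add = report.append
    md = ind.metadata

    if md.status not in Status.__members__:
        add(Issue("META_STATUS_INVALID",
                  f"status {md.status!r} is not one of "
                  f"{', '.join(Status.__members__)}", "metadata.status"))
    elif md.status == Status.DEPRECATED.value:
        add(Issue("META_STATUS_DEPRECATED",
                  "indicator is DEPRECATED; evaluation results are "
                  "informational only", "metadata.status", severity="warning"))
    if not md.indicator_name:
        add(Issue("META_NAME_EMPTY", "indicator name is empty",
                  "metadata.indicator"))
    if any(not t for t in md.translations):
        add(Issue("META_TRANSLATION_EMPTY",
                  "translation list contains an empty language tag",
                  "metadata.translation"))

    seen = set()
    for p in ind.parameters:
        if p.name in seen:
            add(Issue("PARAM_DUPLICATE", f"duplicate parameter {p.name!r}",
                      f"parameter {p.name}"))
        seen.add(p.name)
        if p.param_type not in PARAM_TYPES:
            add(Issue("PARAM_TYPE_INVALID",
                      f"unknown parameter type {p.param_type!r}",
                      f"parameter {p.name}"))
    param_names = {p.name for p in ind.parameters}

    # --- terminology bindings -------------------------------------------
    seen = set()
    for tb in ind.term_bindings:
        loc = f"term binding {tb.local_code}"
        if tb.local_code in seen:
            add(Issue("TERM_DUPLICATE_LOCAL_CODE",
                      f"duplicate terminology local code {tb.local_code!r}", loc))
        seen.add(tb.local_code)
        if not tb.refs:
            add(Issue("TERM_EMPTY_REFS", "binding has no term references", loc))
        for r in tb.refs:
            if not r.system or not r.code:
                add(Issue("TERMREF_INCOMPLETE",
                          "term reference needs both system and code", loc))
            if AT_CODE_RE.match(r.code) and not tb.source_archetype:
                add(Issue("TERM_ATCODE_NO_ARCHETYPE",
                          f"at-code {r.code} bound without a source archetype",
                          loc))
    term_codes = {t.local_code for t in ind.term_bindings}

    # --- archetype bindings ---------------------------------------------
    seen = set()
    for ab in ind.archetype_bindings:
        loc = f"archetype binding {ab.alias}"
        if ab.alias in seen:
            add(Issue("BINDING_ALIAS_DUPLICATE",
                      f"duplicate archetype alias {ab.alias!r}", loc))
        seen.add(ab.alias)
        if not ab.archetype_id:
            add(Issue("BINDING_ARCHETYPE_EMPTY", "archetype id is empty", loc))
        if ab.slot_path and not ab.template_id:
            add(Issue("BINDING_SLOT_WITHOUT_TEMPLATE",
                      "slot path given but no template id", loc))
        codes = set()
        for e in ab.elements:
            if e.element_code in codes:
                add(Issue("ELEMENT_CODE_DUPLICATE",
                          f"duplicate element code {e.element_code!r}", loc))
            codes.add(e.element_code)
            if not e.element_path or not e.element_path.startswith("/"):
                add(Issue("ELEMENT_PATH_INVALID",
                          f"element path {e.element_path!r} must begin with '/'",
                          f"{loc}.{e.element_code}"))

    # --- defines ---------------------------------------------------------
    seen = set()
    for d in ind.defines:
        if d.name.lower() in seen:
            add(Issue("DEFINE_DUPLICATE",
                      f"duplicate define {d.name!r} (names are "
                      "case-insensitive)", f"define {d.name}"))
        seen.add(d.name.lower())

    # --- expression references ------------------------------------------
    memo: dict = {}
    earlier: set[str] = set()

    def check_expr(expr: Expr, scope_alias: Optional[str], loc: str) -> None:
        if isinstance(expr, Retrieve):
            b = ind.binding(expr.alias)
            if b is None:
                add(Issue("REF_UNRESOLVED_ALIAS",
                          f"retrieve references unknown archetype alias "
                          f"{expr.alias!r}", loc))
            if isinstance(expr.term, str) and expr.term not in term_codes:
                add(Issue("REF_UNRESOLVED_TERM",
                          f"retrieve references unknown terminology code "
                          f"{expr.term!r}", loc))
        elif isinstance(expr, Projection):
            src = _source_alias(ind, expr.source, memo)
            if src is not None:
                b = ind.binding(src)
                if b is not None and b.element_path(expr.element_code) is None:
                    add(Issue("REF_UNRESOLVED_ELEMENT",
                              f"element code {expr.element_code!r} not bound "
                              f"in archetype binding {src!r}", loc))
        elif isinstance(expr, NameRef):
            if expr.name in param_names:
                pass
            elif scope_alias is not None:
                b = ind.binding(scope_alias)
                if b is not None and b.element_path(expr.name) is None:
                    add(Issue("REF_UNRESOLVED_NAME",
                              f"{expr.name!r} is neither a parameter nor an "
                              f"element of binding {scope_alias!r}", loc))
            else:
                add(Issue("REF_UNRESOLVED_NAME",
                          f"{expr.name!r} does not resolve to a parameter "
                          "(and no query scope is active)", loc))
        elif isinstance(expr, DefineRef):
            if expr.name.lower() not in {d.name.lower() for d in ind.defines}:
                add(Issue("REF_UNRESOLVED_DEFINE",
                          f"reference to unknown define {expr.name!r}", loc))
            elif loc.startswith("define ") and expr.name.lower() not in earlier:
                add(Issue("DEFINE_FORWARD_REF",
                          f"define references later define {expr.name!r}", loc))
        elif isinstance(expr, (FirstByTime, LastByTime)):
            if expr.key != "entry_time":
                src = _source_alias(ind, expr.source, memo)
                if src is not None:
                    b = ind.binding(src)
                    if b is not None and b.element_path(expr.key) is None:
                        add(Issue("REF_UNRESOLVED_ELEMENT",
                                  f"sort key {expr.key!r} not bound in "
                                  f"{src!r}", loc))

        if isinstance(expr, Filter):
            inner = _source_alias(ind, expr.source, memo)
            check_expr(expr.source, scope_alias, loc)
            check_expr(expr.condition, inner if inner else scope_alias, loc)
        else:
            for c in children(expr):
                check_expr(c, scope_alias, loc)

    for ab in ind.archetype_bindings:
        for pred in ab.predicates:
            check_expr(pred, ab.alias, f"archetype binding {ab.alias} predicate")
    for p in ind.parameters:
        if p.default_value is not None:
            check_expr(p.default_value, None, f"parameter {p.name}")
    for d in ind.defines:
        check_expr(d.body, None, f"define {d.name}")
        earlier.add(d.name.lower())

    # --- population completeness ----------------------------------------
    if ind.measure_type == "proportion":
        for required in ("InitialPopulation", "Denominator", "Numerator"):
            if ind.find_define(required) is None:
                add(Issue("POPULATION_MISSING",
                          f"proportion indicator lacks define {required!r}",
                          "logic"))
    return report


def require_valid(ind: Indicator) -> None:
    report = validate_indicator(ind)
    if not report.ok:
        raise UnvalidatedIndicatorError(report)


def list_required_archetypes(ind: Indicator) -> set[tuple[str, Optional[str]]]:
    """(archetype_id, template_id) pairs of every binding transitively
    reachable from the define statements.  Bindings never retrieved by any
    define are excluded."""
    require_valid(ind)
    aliases: set[str] = set()
    for d in ind.defines:
        for node in walk(d.body):
            if isinstance(node, Retrieve):
                aliases.add(node.alias)
    out = set()
    for ab in ind.archetype_bindings:
        if ab.alias in aliases:
            out.add((ab.archetype_id, ab.template_id))
    return out


def topological_define_order(ind: Indicator) -> list[str]:
    """Evaluation order of defines respecting DefineRef dependencies.

    Independent defines keep their declaration order (stable).  Raises
    :class:`CyclicDefinesError` on any dependency cycle.
    """
    names = [d.name for d in ind.defines]
    index = {n.lower(): i for i, n in enumerate(names)}
    deps: dict[str, set[str]] = {n.lower(): set() for n in names}
    for d in ind.defines:
        for node in walk(d.body):
            if isinstance(node, DefineRef) and node.name.lower() in index:
                if node.name.lower() != d.name.lower():
                    deps[d.name.lower()].add(node.name.lower())

    ordered: list[str] = []
    done: set[str] = set()
    in_progress: set[str] = set()

    def visit(key: str) -> None:
        if key in done:
            return
        if key in in_progress:
            raise CyclicDefinesError(
                f"cyclic define dependency involving {names[index[key]]!r}")
        in_progress.add(key)
        for dep in sorted(deps[key], key=lambda k: index[k]):
            visit(dep)
        in_progress.discard(key)
        done.add(key)
        ordered.append(names[index[key]])

    for n in names:
        visit(n.lower())
    return ordered
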