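"""Evaluation engine: compute an indicator over a clinical data repository.

Evaluation is per patient.  For each patient the engine evaluates the
define statements in topological order (memoized), maps the reserved
population defines onto the standard population sets of a proportion
measure, and scores::

    effective denominator = denominator - exclusions - exceptions
    score = |numerator| / |effective denominator|     (exact rational)

with the numerator intersected with the effective denominator before
scoring.  Count measures instead total the per-patient MeasureObservation
(a boolean counts the patient, a number contributes its value).

Expression semantics follow CQL's three-valued logic: comparisons with
null are null, ``and``/``or`` are Kleene connectives, a null ``where``
condition drops the row, ``exists`` of the empty list is false and
``Count`` of it is 0.  ``Last``/``First`` order by a time key and break
ties by load order.  All computation happens locally after retrieval — the
repository only ever answers path-addressed fetches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction
from typing import Optional, Union

from dateutil.relativedelta import relativedelta

from . import model as m
from .cdr import (Coded, EntryRecord, Quantity, Repository, TimeInterval)
from .model import Indicator, require_valid, topological_define_order
from .terminology import (CodeSystemRegistry, ResolvedValueSet, code_matches,
                          default_registry, resolve_binding)

__all__ = [
    "MeasureResult", "PatientEvaluation", "evaluate_population",
    "evaluate_for_patient", "evaluate_expression", "EvaluationContext",
    "parse_param_value", "EvalTypeError", "MissingParameterError",
    "UnknownPatientError",
]


class EvalTypeError(TypeError):
    """Operator applied to operands it is not defined for."""


class MissingParameterError(ValueError):
    """A parameter without default was not supplied a value."""


class UnknownPatientError(KeyError):
    pass


@dataclass(frozen=True)
class Row:
    """An entry tagged with the alias it was retrieved through, so element
    codes can be resolved against the right binding downstream."""

    alias: str
    rec: EntryRecord


@dataclass
class EvaluationContext:
    """Everything one patient's evaluation needs."""

    indicator: Indicator
    repo: Repository
    patient_id: str
    params: dict[str, object]
    value_sets: dict[str, ResolvedValueSet]
    registry: CodeSystemRegistry
    defines: dict[str, object] = field(default_factory=dict)  # lowercased name
    scope: list[Row] = field(default_factory=list)


POP_FIELDS = ("initial_population", "denominator", "denominator_exclusions",
              "numerator", "numerator_exclusions", "denominator_exceptions")


@dataclass
class MeasureResult:
    """Population sets and score of one evaluation."""

    measure_type: str
    initial_population: set[str]
    denominator: set[str]
    denominator_exclusions: set[str]
    denominator_exceptions: set[str]
    numerator: set[str]
    numerator_exclusions: set[str]
    observations: dict[str, float] = field(default_factory=dict)

    @property
    def effective_denominator_set(self) -> set[str]:
        return (self.denominator - self.denominator_exclusions
                - self.denominator_exceptions)

    @property
    def effective_denominator(self) -> int:
        return len(self.effective_denominator_set)

    @property
    def score(self) -> Optional[Fraction]:
        """|numerator| / effective denominator, or None when undefined."""
        if self.measure_type != "proportion":
            return None
        eff = self.effective_denominator
        if eff == 0:
            return None
        return Fraction(len(self.numerator), eff)

    @property
    def observation_total(self) -> float:
        return sum(self.observations.values())

    def counts(self) -> dict[str, int]:
        out = {f: len(getattr(self, f)) for f in POP_FIELDS}
        out["effective_denominator"] = self.effective_denominator
        return out

    def check_containment(self) -> None:
        """Assert the structural set invariants; raises AssertionError."""
        assert self.denominator <= self.initial_population
        assert self.denominator_exclusions <= self.denominator
        assert self.denominator_exceptions <= self.denominator
        assert self.numerator <= self.effective_denominator_set
        assert self.numerator_exclusions <= self.denominator
        if self.score is not None:
            assert 0 <= self.score <= 1


@dataclass
class PatientEvaluation:
    """Per-patient audit surface: population flags plus every intermediate
    define value."""

    patient_id: str
    flags: dict[str, bool]
    defines: dict[str, object]


# ---------------------------------------------------------------------------
# Scalar coercions and comparisons
# ---------------------------------------------------------------------------

def _singleton(value):
    """CQL-style singleton coercion: [] -> null, [x] -> x; more than one
    element is a type error where a scalar is required."""
    if isinstance(value, list):
        if not value:
            return None
        if len(value) == 1:
            return value[0]
        raise EvalTypeError(
            f"expected a single value, got a list of {len(value)}")
    return value


def _num(value):
    if isinstance(value, Quantity):
        return value.value
    return value


def _compare(op: str, left, right,
             reg: CodeSystemRegistry) -> Optional[bool]:
    left, right = _singleton(left), _singleton(right)
    if left is None or right is None:
        return None
    if isinstance(left, Coded) or isinstance(right, Coded) or \
            isinstance(left, m.TermRef) or isinstance(right, m.TermRef):
        if op not in ("=", "!="):
            raise EvalTypeError(f"cannot order coded values with {op!r}")
        eq = _coded_equal(left, right, reg)
        return eq if op == "=" else (None if eq is None else not eq)
    if isinstance(left, Quantity) and isinstance(right, Quantity):
        if left.unit != right.unit:
            raise EvalTypeError(
                f"cannot compare quantities in {left.unit!r} and "
                f"{right.unit!r}")
    left, right = _num(left), _num(right)
    if isinstance(left, bool) != isinstance(right, bool):
        raise EvalTypeError("cannot compare boolean with non-boolean")
    if isinstance(left, datetime) != isinstance(right, datetime):
        raise EvalTypeError("cannot compare timestamp with non-timestamp")
    if isinstance(left, str) != isinstance(right, str):
        raise EvalTypeError("cannot compare text with non-text")
    try:
        if op == "=":
            return left == right
        if op == "!=":
            return left != right
        if op == "<":
            return left < right
        if op == "<=":
            return left <= right
        if op == ">":
            return left > right
        return left >= right
    except TypeError as exc:  # pragma: no cover - defensive
        raise EvalTypeError(str(exc)) from None


def _coded_equal(left, right, reg: CodeSystemRegistry) -> Optional[bool]:
    def pair(v):
        if isinstance(v, Coded):
            return (v.system, v.code)
        if isinstance(v, m.TermRef):
            return (v.system, v.code)
        raise EvalTypeError(f"cannot compare coded value with "
                            f"{type(v).__name__}")
    (s1, c1), (s2, c2) = pair(left), pair(right)
    if reg.is_registered(s1):
        s1 = reg.canonical(s1)
    if reg.is_registered(s2):
        s2 = reg.canonical(s2)
    return s1 == s2 and c1 == c2


def _kleene_and(a: Optional[bool], b: Optional[bool]) -> Optional[bool]:
    if a is False or b is False:
        return False
    if a is None or b is None:
        return None
    return True


def _kleene_or(a: Optional[bool], b: Optional[bool]) -> Optional[bool]:
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def _as_bool(value) -> Optional[bool]:
    value = _singleton(value)
    if value is None or isinstance(value, bool):
        return value
    raise EvalTypeError(f"expected a boolean, got {type(value).__name__}")


def _as_rows(value) -> list[Row]:
    if value is None:
        return []
    if isinstance(value, Row):
        return [value]
    if isinstance(value, list):
        if value and not all(isinstance(v, Row) for v in value):
            raise EvalTypeError("expected a list of entries")
        return value
    raise EvalTypeError(f"expected entries, got {type(value).__name__}")


# ---------------------------------------------------------------------------
# Expression evaluation
# ---------------------------------------------------------------------------

def evaluate_expression(expr: m.Expr, ctx: EvaluationContext):
    """Evaluate one expression for the context's patient.  Deterministic;
    returns a boolean, number, timestamp, interval, entry list, scalar
    list or None."""
    e = expr
    if isinstance(e, m.Literal):
        return e.value
    if isinstance(e, m.TermRef):
        return e
    if isinstance(e, m.EntryTimeRef):
        if not ctx.scope:
            raise EvalTypeError("entry_time used outside a query scope")
        return ctx.scope[-1].rec.entry_time
    if isinstance(e, m.NameRef):
        return _resolve_name(e.name, ctx)
    if isinstance(e, m.DefineRef):
        key = e.name.lower()
        if key not in ctx.defines:
            d = ctx.indicator.find_define(e.name)
            if d is None:
                raise EvalTypeError(f"unknown define {e.name!r}")
            ctx.defines[key] = evaluate_expression(d.body, ctx)
        return ctx.defines[key]
    if isinstance(e, m.Retrieve):
        return _retrieve(e, ctx)
    if isinstance(e, m.Projection):
        return _project(evaluate_expression(e.source, ctx), e.element_code,
                        ctx)
    if isinstance(e, m.Filter):
        rows = _as_rows(evaluate_expression(e.source, ctx))
        out = []
        for row in rows:
            ctx.scope.append(row)
            try:
                keep = _as_bool(evaluate_expression(e.condition, ctx))
            finally:
                ctx.scope.pop()
            if keep is True:          # null condition drops the row
                out.append(row)
        return out
    if isinstance(e, m.Exists):
        v = evaluate_expression(e.operand, ctx)
        if v is None:
            return False
        if isinstance(v, list):
            return len(v) > 0
        return True
    if isinstance(e, m.Count):
        v = evaluate_expression(e.operand, ctx)
        if v is None:
            return 0
        if isinstance(v, list):
            return len(v)
        return 1
    if isinstance(e, (m.FirstByTime, m.LastByTime)):
        return _first_last(e, ctx)
    if isinstance(e, m.Not):
        v = _as_bool(evaluate_expression(e.operand, ctx))
        return None if v is None else not v
    if isinstance(e, m.Binary):
        return _binary(e, ctx)
    if isinstance(e, m.During):
        return _during(e, ctx)
    if isinstance(e, m.IntervalLit):
        low = _expect_time(evaluate_expression(e.low, ctx), "interval bound")
        high = _expect_time(evaluate_expression(e.high, ctx),
                            "interval bound")
        return TimeInterval(low=low, high=high, low_closed=e.low_closed,
                            high_closed=e.high_closed)
    if isinstance(e, m.AgeInYearsAt):
        birth = _expect_time(evaluate_expression(e.birth, ctx), "birth date")
        at = _expect_time(evaluate_expression(e.at, ctx), "age anchor")
        if birth is None or at is None:
            return None
        return relativedelta(at, birth).years
    if isinstance(e, m.SetOp):
        return _setop(e, ctx)
    if isinstance(e, m.TimeShift):
        base = _expect_time(evaluate_expression(e.base, ctx), "time shift")
        if base is None:
            return None
        return base + relativedelta(**{e.unit: e.amount})
    if isinstance(e, m.Start):
        v = _singleton(evaluate_expression(e.operand, ctx))
        if v is None:
            return None
        if not isinstance(v, TimeInterval):
            raise EvalTypeError("'start of' needs an interval")
        return v.low
    if isinstance(e, m.End):
        v = _singleton(evaluate_expression(e.operand, ctx))
        if v is None:
            return None
        if not isinstance(v, TimeInterval):
            raise EvalTypeError("'end of' needs an interval")
        return v.high
    raise EvalTypeError(f"cannot evaluate {type(e).__name__}")


def _expect_time(value, what: str) -> Optional[datetime]:
    value = _singleton(value)
    if value is None or isinstance(value, datetime):
        return value
    raise EvalTypeError(f"{what} must be a timestamp, "
                        f"got {type(value).__name__}")


def _resolve_name(name: str, ctx: EvaluationContext):
    # innermost query scope wins over parameters
    for row in reversed(ctx.scope):
        binding = ctx.indicator.binding(row.alias)
        if binding is not None:
            path = binding.element_path(name)
            if path is not None:
                return row.rec.values.get(path)
    if name in ctx.params:
        return ctx.params[name]
    raise EvalTypeError(f"{name!r} is neither an in-scope element code nor "
                        "a parameter")


def _retrieve(e: m.Retrieve, ctx: EvaluationContext) -> list[Row]:
    binding = ctx.indicator.binding(e.alias)
    if binding is None:
        raise EvalTypeError(f"unknown archetype alias {e.alias!r}")
    recs = ctx.repo.rows_for_patient(binding.archetype_id,
                                     binding.template_id, ctx.patient_id)
    if e.term is not None:
        if isinstance(e.term, str):
            vs = ctx.value_sets.get(e.term)
            if vs is None:
                raise EvalTypeError(f"unknown terminology code {e.term!r}")
        else:
            system = e.term.system
            if ctx.registry.is_registered(system):
                system = ctx.registry.canonical(system)
            vs = ResolvedValueSet(local_code="<inline>", members=frozenset(
                [m.TermRef(system=system, code=e.term.code)]))
        recs = [r for r in recs if _entry_matches_term(r, vs, ctx.registry)]
    rows = [Row(alias=e.alias, rec=r) for r in recs]
    for pred in binding.predicates:
        kept = []
        for row in rows:
            ctx.scope.append(row)
            try:
                ok = _as_bool(evaluate_expression(pred, ctx))
            finally:
                ctx.scope.pop()
            if ok is True:
                kept.append(row)
        rows = kept
    return rows


def _entry_matches_term(rec: EntryRecord, vs: ResolvedValueSet,
                        reg: CodeSystemRegistry) -> bool:
    # an entry satisfies a term constraint when ANY of its coded element
    # values belongs to the value set
    return any(isinstance(v, Coded)
               and code_matches((v.system, v.code), vs, reg)
               for v in rec.values.values())


def _project(value, code: str, ctx: EvaluationContext):
    def one(row: Row):
        binding = ctx.indicator.binding(row.alias)
        path = binding.element_path(code) if binding else None
        if path is None:
            raise EvalTypeError(
                f"element code {code!r} is not bound in {row.alias!r}")
        return row.rec.values.get(path)
    if value is None:
        return None
    if isinstance(value, Row):
        return one(value)
    if isinstance(value, list):
        return [one(r) for r in _as_rows(value)]
    raise EvalTypeError(f"cannot project {code!r} from "
                        f"{type(value).__name__}")


def _sort_time(row: Row, key: str, ctx: EvaluationContext
               ) -> Optional[datetime]:
    if key == "entry_time":
        return row.rec.entry_time
    binding = ctx.indicator.binding(row.alias)
    path = binding.element_path(key) if binding else None
    if path is None:
        raise EvalTypeError(f"sort key {key!r} is not bound in "
                            f"{row.alias!r}")
    v = row.rec.values.get(path)
    if v is None or isinstance(v, datetime):
        return v
    raise EvalTypeError(f"sort key {key!r} is not a timestamp")


def _first_last(e, ctx: EvaluationContext) -> Optional[Row]:
    rows = _as_rows(evaluate_expression(e.source, ctx))
    best: Optional[Row] = None
    best_t: Optional[datetime] = None
    last = isinstance(e, m.LastByTime)
    for row in rows:                      # load order; ties -> load order
        t = _sort_time(row, e.key, ctx)
        if t is None:
            continue
        if best_t is None or (t >= best_t if last else t < best_t):
            best, best_t = row, t
    return best


def _binary(e: m.Binary, ctx: EvaluationContext):
    if e.op == "and":
        return _kleene_and(_as_bool(evaluate_expression(e.left, ctx)),
                           _as_bool(evaluate_expression(e.right, ctx)))
    if e.op == "or":
        return _kleene_or(_as_bool(evaluate_expression(e.left, ctx)),
                          _as_bool(evaluate_expression(e.right, ctx)))
    left = evaluate_expression(e.left, ctx)
    right = evaluate_expression(e.right, ctx)
    if e.op in ("=", "!=", "<", "<=", ">", ">="):
        return _compare(e.op, left, right, ctx.registry)
    left, right = _num(_singleton(left)), _num(_singleton(right))
    if left is None or right is None:
        return None
    if not isinstance(left, (int, float)) or not isinstance(
            right, (int, float)) or isinstance(left, bool) or \
            isinstance(right, bool):
        raise EvalTypeError(f"arithmetic {e.op!r} needs numbers")
    if e.op == "+":
        return left + right
    if e.op == "-":
        return left - right
    if e.op == "*":
        return left * right
    if right == 0:
        return None                       # division by zero is null
    return left / right


def _during(e: m.During, ctx: EvaluationContext) -> Optional[bool]:
    operand = _singleton(evaluate_expression(e.operand, ctx))
    interval = _singleton(evaluate_expression(e.interval, ctx))
    if operand is None or interval is None:
        return None
    if not isinstance(interval, TimeInterval):
        raise EvalTypeError("'during' needs an interval on the right")
    if isinstance(operand, TimeInterval):
        return interval.contains_interval(operand)
    if isinstance(operand, datetime):
        return interval.contains(operand)
    raise EvalTypeError("'during' needs a timestamp or interval on the left")


def _setop(e: m.SetOp, ctx: EvaluationContext) -> list[Row]:
    left = _as_rows(evaluate_expression(e.left, ctx))
    right = _as_rows(evaluate_expression(e.right, ctx))
    right_uids = {r.rec.uid for r in right}
    if e.op == "union":
        seen = {r.rec.uid for r in left}
        extra = [r for r in right if r.rec.uid not in seen]
        return left + extra
    if e.op == "intersect":
        return [r for r in left if r.rec.uid in right_uids]
    return [r for r in left if r.rec.uid not in right_uids]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def parse_param_value(decl: m.ParameterDecl, text: str):
    """Parse a CLI-style parameter override.  Intervals are written
    ``start..end`` (closed-open), timestamps are ISO-8601, coded values
    ``system|code``."""
    if decl.param_type == "Interval<DateTime>":
        if ".." not in text:
            raise MissingParameterError(
                f"{decl.name}: interval must be written start..end")
        lo, hi = text.split("..", 1)
        return TimeInterval(low=datetime.fromisoformat(lo.strip()),
                            high=datetime.fromisoformat(hi.strip()))
    if decl.param_type == "DateTime":
        return datetime.fromisoformat(text)
    if decl.param_type == "Integer":
        return int(text)
    if decl.param_type == "Decimal":
        return float(text)
    if decl.param_type == "Code":
        if "|" not in text:
            raise MissingParameterError(
                f"{decl.name}: code must be written system|code")
        system, code = text.split("|", 1)
        return Coded(system=system, code=code)
    return text


def _resolve_params(ind: Indicator, supplied: Optional[dict],
                    base_ctx: EvaluationContext) -> dict[str, object]:
    params: dict[str, object] = {}
    supplied = dict(supplied or {})
    for decl in ind.parameters:
        if decl.name in supplied:
            value = supplied.pop(decl.name)
            if isinstance(value, str) and decl.param_type != "String":
                value = parse_param_value(decl, value)
            params[decl.name] = value
        elif decl.default_value is not None:
            params[decl.name] = evaluate_expression(decl.default_value,
                                                    base_ctx)
        else:
            raise MissingParameterError(
                f"parameter {decl.name!r} has no default and no supplied "
                "value")
    if supplied:
        raise MissingParameterError(
            f"unknown parameter(s): {', '.join(sorted(supplied))}")
    return params


# ---------------------------------------------------------------------------
# Population evaluation
# ---------------------------------------------------------------------------

def _prepare(ind: Indicator, repo: Repository,
             params: Optional[dict],
             registry: Optional[CodeSystemRegistry]):
    require_valid(ind)
    registry = registry or default_registry()
    value_sets = {tb.local_code: resolve_binding(tb, registry)
                  for tb in ind.term_bindings}
    base_ctx = EvaluationContext(indicator=ind, repo=repo, patient_id="",
                                 params={}, value_sets=value_sets,
                                 registry=registry)
    resolved = _resolve_params(ind, params, base_ctx)
    order = topological_define_order(ind)
    return registry, value_sets, resolved, order


def _evaluate_patient(ind, repo, pid, value_sets, params, registry, order
                      ) -> EvaluationContext:
    ctx = EvaluationContext(indicator=ind, repo=repo, patient_id=pid,
                            params=params, value_sets=value_sets,
                            registry=registry)
    for name in order:
        d = ind.find_define(name)
        ctx.defines[name.lower()] = evaluate_expression(d.body, ctx)
    return ctx


def _flag(ctx: EvaluationContext, define: str) -> bool:
    v = ctx.defines.get(define.lower())
    return v is True


def resolve_parameters(ind: Indicator, repo: Repository,
                       params: Optional[dict] = None,
                       registry: Optional[CodeSystemRegistry] = None
                       ) -> dict[str, object]:
    """Effective parameter values: supplied overrides (strings parsed per
    declared type) merged with evaluated defaults."""
    _, _, resolved, _ = _prepare(ind, repo, params, registry)
    return resolved


def evaluate_for_patient(ind: Indicator, repo: Repository, patient_id: str,
                         params: Optional[dict] = None,
                         registry: Optional[CodeSystemRegistry] = None
                         ) -> PatientEvaluation:
    """Evaluate every define for one patient; exposes intermediate values
    for audit.  Consistent with :func:`evaluate_population` restricted to
    that patient."""
    registry, value_sets, resolved, order = _prepare(ind, repo, params,
                                                     registry)
    if patient_id not in repo.patients():
        raise UnknownPatientError(patient_id)
    ctx = _evaluate_patient(ind, repo, patient_id, value_sets, resolved,
                            registry, order)
    flags = {name: _flag(ctx, name) for name in m.POPULATION_NAMES
             if ind.find_define(name) is not None}
    return PatientEvaluation(patient_id=patient_id, flags=flags,
                             defines={name: ctx.defines[name.lower()]
                                      for name in order})


def evaluate_population(ind: Indicator, repo: Repository,
                        params: Optional[dict] = None,
                        registry: Optional[CodeSystemRegistry] = None
                        ) -> MeasureResult:
    """Evaluate an indicator over every patient in the repository.

    Population sets are nested by construction: the denominator is
    intersected with the initial population, exclusion/exception sets with
    the denominator, and the numerator with the effective denominator.
    """
    registry, value_sets, resolved, order = _prepare(ind, repo, params,
                                                     registry)
    ip: set[str] = set()
    denom: set[str] = set()
    dx: set[str] = set()
    de: set[str] = set()
    num_raw: set[str] = set()
    nx_raw: set[str] = set()
    observations: dict[str, float] = {}
    is_count = ind.measure_type == "count"

    for pid in repo.patients():
        ctx = _evaluate_patient(ind, repo, pid, value_sets, resolved,
                                registry, order)
        if is_count:
            v = ctx.defines.get("measureobservation")
            if v is True:
                observations[pid] = 1.0
            elif isinstance(v, (int, float)) and not isinstance(v, bool):
                observations[pid] = float(v)
            continue
        if _flag(ctx, "InitialPopulation"):
            ip.add(pid)
            if _flag(ctx, "Denominator"):
                denom.add(pid)
                if _flag(ctx, "DenominatorExclusions"):
                    dx.add(pid)
                if _flag(ctx, "DenominatorExceptions"):
                    de.add(pid)
                if _flag(ctx, "Numerator"):
                    num_raw.add(pid)
                if _flag(ctx, "NumeratorExclusions"):
                    nx_raw.add(pid)

    if is_count:
        return MeasureResult(measure_type="count", initial_population=set(),
                             denominator=set(), denominator_exclusions=set(),
                             denominator_exceptions=set(), numerator=set(),
                             numerator_exclusions=set(),
                             observations=observations)

    effective = denom - dx - de
    numerator = (num_raw & effective) - nx_raw
    result = MeasureResult(
        measure_type="proportion",
        initial_population=ip,
        denominator=denom,
        denominator_exclusions=dx,
        denominator_exceptions=de,
        numerator=numerator,
        numerator_exclusions=nx_raw & denom,
    )
    result.check_containment()
    return result
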