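"""Seeded random generator of valid indicator artifacts.

Used by the serialization round-trip property tests: any artifact this
builder produces must validate cleanly, serialize to text and XML, and
reparse field-identically.  Expressions are generated with reference
discipline (parameters, earlier defines, and filter-scoped element codes
only) but deliberately without static typing — the language itself has
none; type errors surface at evaluation.
"""

from __future__ import annotations

import string
from datetime import datetime, timedelta
from random import Random

from cqi.model import (
    AgeInYearsAt, ArchetypeBinding, Binary, Count, DefineRef,
    DefineStatement, During, ElementBinding, End, EntryTimeRef, Exists,
    Filter, FirstByTime, Indicator, IntervalLit, LastByTime, Literal,
    MetadataBlock, NameRef, Not, ParameterDecl, Projection, Retrieve,
    SetOp, Start, TermBinding, TermRef, TimeShift,
)

_WORDS = ("care", "visit", "score", "plan", "event", "case", "stay",
          "dose", "lab", "exam")
_SYSTEMS = (("ICD-10", "http://hl7.org/fhir/sid/icd-10"),
            ("SNOMED-CT", "http://snomed.info/sct"),
            ("LOINC", "http://loinc.org"))


def _name(rng: Random, prefix: str = "") -> str:
    return prefix + rng.choice(_WORDS).capitalize() + str(rng.randint(1, 99))


def _code(rng: Random) -> str:
    return (rng.choice(string.ascii_uppercase)
            + "".join(rng.choice(string.digits) for _ in range(3))
            + (("." + rng.choice(string.digits)) if rng.random() < 0.4
               else ""))


def _dt(rng: Random) -> datetime:
    base = datetime(2012, 1, 1)
    return base + timedelta(seconds=rng.randrange(8 * 365 * 86400))


class _Ctx:
    def __init__(self, rng: Random, params, bindings, earlier, terms=()):
        self.rng = rng
        self.params = params
        self.bindings = bindings
        self.earlier = earlier
        self.terms = list(terms)


def _literal(rng: Random) -> Literal:
    kind = rng.randrange(6)
    if kind == 0:
        return Literal(value=rng.randint(-500, 500), value_type="Integer")
    if kind == 1:
        return Literal(value=round(rng.uniform(-100, 300), 3),
                       value_type="Decimal")
    if kind == 2:
        return Literal(value=_name(rng) + "'s \"note\"\n",
                       value_type="String")
    if kind == 3:
        return Literal(value=_dt(rng), value_type="DateTime")
    if kind == 4:
        return Literal(value=rng.random() < 0.5, value_type="Boolean")
    return Literal(value=None, value_type="Null")


def _retrieve(ctx: _Ctx) -> Retrieve:
    rng = ctx.rng
    binding = rng.choice(ctx.bindings)
    term = None
    r = rng.random()
    if r < 0.4:
        term = TermRef(system="ICD-10", code=_code(rng),
                       system_uri="http://hl7.org/fhir/sid/icd-10")
    elif r < 0.7 and ctx.terms:
        term = rng.choice(ctx.terms)
    return Retrieve(alias=binding.alias, term=term)


def _query(ctx: _Ctx, depth: int):
    """An entry-list expression with a statically known source alias."""
    rng = ctx.rng
    src = _retrieve(ctx)
    binding = next(b for b in ctx.bindings if b.alias == src.alias)
    if depth > 0 and rng.random() < 0.6:
        cond = _expr(ctx, depth - 1, scope=binding)
        return Filter(source=src, condition=cond), binding
    return src, binding


def _scalar_or_literal(ctx: _Ctx, depth: int, scope):
    if depth <= 0:
        return _literal(ctx.rng)
    return _expr(ctx, depth - 1, scope)


def _expr(ctx: _Ctx, depth: int, scope=None):
    rng = ctx.rng
    if depth <= 0:
        choices = ["literal", "param", "name"]
    else:
        choices = ["literal", "param", "name", "define", "exists", "count",
                   "not", "binary", "during", "interval", "age", "shift",
                   "startend", "firstlast", "project", "setop"]
    while True:
        kind = rng.choice(choices)
        if kind == "literal":
            return _literal(rng)
        if kind == "param":
            if not ctx.params:
                continue
            return NameRef(name=rng.choice(ctx.params).name)
        if kind == "name":
            if scope is not None and scope.elements and rng.random() < 0.7:
                return NameRef(
                    name=rng.choice(scope.elements).element_code)
            if scope is not None and rng.random() < 0.3:
                return EntryTimeRef()
            if ctx.params:
                return NameRef(name=rng.choice(ctx.params).name)
            continue
        if kind == "define":
            if not ctx.earlier:
                continue
            return DefineRef(name=rng.choice(ctx.earlier))
        if kind == "exists":
            q, _ = _query(ctx, depth - 1)
            return Exists(operand=q)
        if kind == "count":
            q, _ = _query(ctx, depth - 1)
            return Count(operand=q)
        if kind == "not":
            return Not(operand=_expr(ctx, depth - 1, scope))
        if kind == "binary":
            op = rng.choice(("=", "!=", "<", "<=", ">", ">=", "and", "or",
                             "+", "-", "*", "/"))
            return Binary(op=op, left=_expr(ctx, depth - 1, scope),
                          right=_expr(ctx, depth - 1, scope))
        if kind == "during":
            return During(operand=_expr(ctx, depth - 1, scope),
                          interval=_expr(ctx, depth - 1, scope))
        if kind == "interval":
            return IntervalLit(low=_scalar_or_literal(ctx, depth, scope),
                               high=_scalar_or_literal(ctx, depth, scope),
                               low_closed=rng.random() < 0.5,
                               high_closed=rng.random() < 0.5)
        if kind == "age":
            return AgeInYearsAt(birth=_expr(ctx, depth - 1, scope),
                                at=_expr(ctx, depth - 1, scope))
        if kind == "shift":
            return TimeShift(base=_expr(ctx, depth - 1, scope),
                             amount=rng.randint(-48, 48),
                             unit=rng.choice(("hours", "days", "months",
                                              "years")))
        if kind == "startend":
            cls = Start if rng.random() < 0.5 else End
            return cls(operand=_expr(ctx, depth - 1, scope))
        if kind == "firstlast":
            q, binding = _query(ctx, depth - 1)
            cls = FirstByTime if rng.random() < 0.5 else LastByTime
            key = "entry_time"
            if binding.elements and rng.random() < 0.4:
                key = rng.choice(binding.elements).element_code
            return cls(source=q, key=key)
        if kind == "project":
            q, binding = _query(ctx, depth - 1)
            if not binding.elements:
                continue
            return Projection(
                source=q,
                element_code=rng.choice(binding.elements).element_code)
        if kind == "setop":
            left, _ = _query(ctx, depth - 1)
            right, _ = _query(ctx, depth - 1)
            return SetOp(op=rng.choice(("union", "intersect", "except")),
                         left=left, right=right)


def random_indicator(seed: int) -> Indicator:
    """A random valid indicator artifact, fully determined by the seed."""
    rng = Random(seed)

    metadata = MetadataBlock(
        indicator_name=_name(rng, "Measure "),
        version=f"{rng.randint(0, 3)}.{rng.randint(0, 9)}.{rng.randint(0, 9)}",
        language=rng.choice(("en", "zh-CN", "nl")),
        translations=rng.sample(["en", "zh-CN", "de", "fr"],
                                rng.randint(0, 3)),
        description=("Auto-built artifact with \"quotes\", a \\ slash "
                     "and a\nline break." if rng.random() < 0.5 else ""),
        status=rng.choice(("DRAFT", "REVIEWING", "PUBLISHED")),
        author=_name(rng, "Dr. ") if rng.random() < 0.7 else "",
        time=_dt(rng) if rng.random() < 0.7 else None,
        email="author@example.org" if rng.random() < 0.5 else "",
    )

    params = [ParameterDecl(
        name="MeasurementPeriod", param_type="Interval<DateTime>",
        default_value=IntervalLit(
            low=Literal(value=datetime(2016, 1, 1), value_type="DateTime"),
            high=Literal(value=datetime(2017, 1, 1), value_type="DateTime")))]
    for _ in range(rng.randint(0, 2)):
        ptype = rng.choice(("Integer", "Decimal", "String", "DateTime"))
        default = None
        if rng.random() < 0.6:
            default = {"Integer": Literal(value=rng.randint(0, 99),
                                          value_type="Integer"),
                       "Decimal": Literal(value=round(rng.uniform(0, 9), 2),
                                          value_type="Decimal"),
                       "String": Literal(value=_name(rng),
                                         value_type="String"),
                       "DateTime": Literal(value=_dt(rng),
                                           value_type="DateTime")}[ptype]
        params.append(ParameterDecl(name=_name(rng, "P"), param_type=ptype,
                                    default_value=default))
    seen = set()
    params = [p for p in params
              if not (p.name in seen or seen.add(p.name))]

    bindings = []
    for i in range(rng.randint(1, 4)):
        archetype_id = (f"openEHR-EHR-OBSERVATION."
                        f"{rng.choice(_WORDS)}_{rng.choice(_WORDS)}.v"
                        f"{rng.randint(0, 2)}")
        template_id = None
        slot = ""
        if rng.random() < 0.4:
            template_id = f"{rng.choice(_WORDS)}_report.t.v1"
            if rng.random() < 0.5:
                slot = f"/content[{archetype_id}]"
        elements = [ElementBinding(
            element_code=f"E{i:01d}{j:03d}",
            element_path=f"/data[at0001]/items[at{j + 2:04d}]/value")
            for j in range(rng.randint(1, 4))]
        bindings.append(ArchetypeBinding(
            alias=f"AB{i:04d}", archetype_id=archetype_id,
            template_id=template_id, slot_path=slot, elements=elements))

    terms = []
    for i in range(rng.randint(0, 3)):
        if rng.random() < 0.3 and bindings:
            src = rng.choice(bindings).archetype_id
            lo = rng.randint(1, 20)
            hi = lo + rng.randint(0, 8)
            code = (f"at{lo:04d}-at{hi:04d}" if hi > lo else f"at{lo:04d}")
            refs = [TermRef(system=src, code=code)]
            terms.append(TermBinding(local_code=f"TB{i:04d}", refs=refs,
                                     source_archetype=src))
        else:
            system, uri = rng.choice(_SYSTEMS)
            refs = [TermRef(system=system, code=_code(rng), system_uri=uri)
                    for _ in range(rng.randint(1, 3))]
            terms.append(TermBinding(local_code=f"TB{i:04d}", refs=refs))

    ctx = _Ctx(rng, params, bindings, earlier=[])
    ctx.terms = [t.local_code for t in terms]

    # add predicates now that term codes exist
    for b in bindings:
        if rng.random() < 0.4:
            b.predicates = [_expr(ctx, 1, scope=b)
                            for _ in range(rng.randint(1, 2))]

    defines = []
    for _ in range(rng.randint(0, 3)):
        name = _name(rng, "Def ")
        if any(d.name.lower() == name.lower() for d in defines):
            continue
        defines.append(DefineStatement(name=name,
                                       body=_expr(ctx, rng.randint(1, 3))))
        ctx.earlier = [d.name for d in defines]
    for pop in ("InitialPopulation", "Denominator", "Numerator"):
        defines.append(DefineStatement(name=pop,
                                       body=_expr(ctx, rng.randint(1, 2))))
        ctx.earlier = [d.name for d in defines]

    return Indicator(metadata=metadata, parameters=params,
                     term_bindings=terms, archetype_bindings=bindings,
                     defines=defines)
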