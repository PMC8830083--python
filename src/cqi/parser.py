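"""Lexer, parser and canonical serializer for the indicator language.

An indicator source file (``.cqi``, UTF-8) has four sections::

    metadata       management metadata (name, version, status, ...)
    terminology    local term codes bound to external or archetype terms
    archetypes     local aliases bound to openEHR archetypes/templates
    logic          parameters and named define statements (CQL-style)

The expression sub-language is a CQL subset: retrieves ``[ALIAS : TERM]``,
``where`` filters, ``exists``/``Count``/``First``/``Last``, ``Interval[a, b)``
literals with explicit bound inclusivity, ``during``, boolean connectives,
comparisons, ``AgeInYearsAt``, calendar shifts (``+ 6 months``) and
``start of`` / ``end of``.  Strings follow CQL conventions: double quotes
name things (defines), single quotes are text literals.  ``//`` starts a
comment.  Keywords are lowercase and case-sensitive; define names are
case-insensitive only for population lookup.

``parse_indicator`` and ``serialize_text`` are inverse on valid artifacts:
the serializer emits canonical formatting whose reparse is field-identical
to the input AST.
"""

from __future__ import annotations

import re
from datetime import datetime
from typing import Optional, Union

from .model import (
    AgeInYearsAt, ArchetypeBinding, Binary, Count, DefineRef, DefineStatement,
    During, ElementBinding, End, EntryTimeRef, Exists, Expr, Filter,
    FirstByTime, Indicator, IntervalLit, LastByTime, Literal, MetadataBlock,
    NameRef, Not, ParameterDecl, Projection, Retrieve, SetOp, SourceSpan,
    Start, TermBinding, TermRef, TimeShift, TIME_UNITS,
    UnvalidatedIndicatorError, require_valid,
)
from .terminology import CodeSystemRegistry, default_registry

__all__ = [
    "parse_indicator", "parse_expression", "serialize_text",
    "parse_term_shorthand", "CqiSyntaxError", "ShorthandError",
]


class CqiSyntaxError(SyntaxError):
    """Parse failure with a source position and an expected-token hint."""

    def __init__(self, message: str, span: SourceSpan,
                 expected: Optional[str] = None):
        hint = f" (expected {expected})" if expected else ""
        super().__init__(f"{message} at {span}{hint}")
        self.span = span
        self.expected = expected


class ShorthandError(ValueError):
    """Malformed or unresolvable ``SYSTEM::[CODE]`` term shorthand."""


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")
BARE_DT_RE = re.compile(r"[0-9][0-9:T.\-]*")

TWO_CHAR = ("::", "<=", ">=", "!=")
ONE_CHAR = ":;,.(){}[]=<>+-*/"

RESERVED = {
    "metadata", "terminology", "archetypes", "logic",
    "term", "uri", "bind", "archetype", "name", "in", "template", "with",
    "path", "elements", "predicates", "parameter", "default", "define",
    "where", "sort", "by", "exists", "not", "and", "or", "union",
    "intersect", "except", "during", "start", "end", "of",
    "true", "false", "null", "Interval", "Count", "First", "Last",
    "AgeInYearsAt", "entry_time",
} | set(TIME_UNITS)

META_KEYS = ("indicator", "version", "language", "translation",
             "description", "status", "author", "time", "email")


class Token:
    __slots__ = ("kind", "value", "span")

    def __init__(self, kind: str, value, span: SourceSpan):
        self.kind = kind      # IDENT DQSTRING SQSTRING NUMBER DATETIME OP EOF
        self.value = value
        self.span = span

    def __repr__(self):  # pragma: no cover
        return f"Token({self.kind}, {self.value!r})"


def _unescape(raw: str) -> str:
    return (raw.replace("\\n", "\n").replace("\\t", "\t")
               .replace('\\"', '"').replace("\\'", "'")
               .replace("\\\\", "\\"))


def escape_string(s: str) -> str:
    return (s.replace("\\", "\\\\").replace('"', '\\"')
             .replace("\n", "\\n").replace("\t", "\\t"))


def escape_sq(s: str) -> str:
    return (s.replace("\\", "\\\\").replace("'", "\\'")
             .replace("\n", "\\n").replace("\t", "\\t"))


class Lexer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self._cache: Optional[Token] = None
        self._line_starts = [0]
        for i, ch in enumerate(text):
            if ch == "\n":
                self._line_starts.append(i + 1)

    def span_at(self, pos: int, length: int = 0) -> SourceSpan:
        lo, hi = 0, len(self._line_starts) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self._line_starts[mid] <= pos:
                lo = mid
            else:
                hi = mid - 1
        return SourceSpan(line=lo + 1, column=pos - self._line_starts[lo] + 1,
                          length=length)

    def _skip_trivia(self) -> None:
        t = self.text
        n = len(t)
        while self.pos < n:
            ch = t[self.pos]
            if ch in " \t\r\n":
                self.pos += 1
            elif ch == "/" and self.pos + 1 < n and t[self.pos + 1] == "/":
                while self.pos < n and t[self.pos] != "\n":
                    self.pos += 1
            else:
                break

    def peek(self) -> Token:
        if self._cache is None:
            self._cache = self._scan()
        return self._cache

    def advance(self) -> Token:
        tok = self.peek()
        self._cache = None
        return tok

    def _scan(self) -> Token:
        self._skip_trivia()
        t, n = self.text, len(self.text)
        start = self.pos
        if start >= n:
            return Token("EOF", None, self.span_at(start))
        ch = t[start]

        if ch in '"\'':
            return self._scan_string(ch)
        if ch == "@":
            return self._scan_datetime()
        m = IDENT_RE.match(t, start)
        if m:
            self.pos = m.end()
            return Token("IDENT", m.group(),
                         self.span_at(start, m.end() - start))
        m = NUMBER_RE.match(t, start)
        if m:
            self.pos = m.end()
            return Token("NUMBER", m.group(),
                         self.span_at(start, m.end() - start))
        two = t[start:start + 2]
        if two in TWO_CHAR:
            self.pos = start + 2
            return Token("OP", two, self.span_at(start, 2))
        if ch in ONE_CHAR:
            self.pos = start + 1
            return Token("OP", ch, self.span_at(start, 1))
        raise CqiSyntaxError(f"unexpected character {ch!r}",
                             self.span_at(start, 1))

    def _scan_string(self, quote: str) -> Token:
        t, n = self.text, len(self.text)
        start = self.pos
        i = start + 1
        buf = []
        while i < n:
            ch = t[i]
            if ch == "\\" and i + 1 < n:
                buf.append(t[i:i + 2])
                i += 2
                continue
            if ch == quote:
                self.pos = i + 1
                kind = "DQSTRING" if quote == '"' else "SQSTRING"
                return Token(kind, _unescape("".join(buf)),
                             self.span_at(start, i + 1 - start))
            if ch == "\n":
                break
            buf.append(ch)
            i += 1
        raise CqiSyntaxError("unterminated string literal",
                             self.span_at(start))

    def _scan_datetime(self) -> Token:
        t = self.text
        start = self.pos
        i = start + 1
        if i < len(t) and t[i] == '"':
            self.pos = i
            inner = self._scan_string('"')
            raw = inner.value
        else:
            m = BARE_DT_RE.match(t, i)
            if not m:
                raise CqiSyntaxError("malformed date-time literal",
                                     self.span_at(start))
            raw = m.group()
            self.pos = m.end()
        try:
            value = datetime.fromisoformat(raw)
        except ValueError:
            raise CqiSyntaxError(f"invalid date-time {raw!r}",
                                 self.span_at(start)) from None
        return Token("DATETIME", value, self.span_at(start, self.pos - start))

    def raw_until_rbracket(self) -> tuple[str, SourceSpan]:
        """Capture raw text up to (and consuming) the next ``]``.

        Used for code lists, whose tokens (``N18.6``, ``at0014-at0022``)
        do not follow identifier lexing rules.
        """
        assert self._cache is None, "raw scan with buffered lookahead"
        t = self.text
        start = self.pos
        idx = t.find("]", start)
        if idx < 0:
            raise CqiSyntaxError("unterminated code list",
                                 self.span_at(start))
        self.pos = idx + 1
        return t[start:idx], self.span_at(start, idx - start)


# ---------------------------------------------------------------------------
# Term shorthand
# ---------------------------------------------------------------------------

SHORTHAND_RE = re.compile(r"^([A-Za-z][A-Za-z0-9.\-]*)::\[([^\]\s]+)\]$")


def parse_term_shorthand(token: str,
                         registry: Optional[CodeSystemRegistry] = None
                         ) -> TermRef:
    """Parse ``ICD10::[N185]`` into a :class:`TermRef` with the system
    alias resolved to its registered canonical name."""
    registry = registry or default_registry()
    m = SHORTHAND_RE.match(token.strip())
    if not m:
        raise ShorthandError(
            f"{token!r} does not match the SYSTEM::[CODE] pattern")
    system, code = m.group(1), m.group(2)
    if not registry.is_registered(system):
        raise ShorthandError(f"unregistered code system {system!r}")
    canonical = registry.canonical(system)
    return TermRef(system=canonical, code=code,
                   system_uri=registry.uri(canonical))


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

CMP_OPS = ("=", "!=", "<", "<=", ">", ">=")
PARAM_TYPE_IDENTS = ("DateTime", "Integer", "Decimal", "String", "Code")


class _Parser:
    def __init__(self, text: str, registry: CodeSystemRegistry):
        self.lex = Lexer(text)
        self.reg = registry

    # -- token helpers ----------------------------------------------------
    def peek(self) -> Token:
        return self.lex.peek()

    def at_ident(self, *names: str) -> bool:
        tok = self.peek()
        return tok.kind == "IDENT" and tok.value in names

    def expect_op(self, op: str) -> Token:
        tok = self.lex.advance()
        if tok.kind != "OP" or tok.value != op:
            raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                                 expected=repr(op))
        return tok

    def expect_kw(self, kw: str) -> Token:
        tok = self.lex.advance()
        if tok.kind != "IDENT" or tok.value != kw:
            raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                                 expected=f"keyword {kw!r}")
        return tok

    def expect_ident(self, what: str = "identifier") -> Token:
        tok = self.lex.advance()
        if tok.kind != "IDENT":
            raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                                 expected=what)
        return tok

    def expect_string(self, what: str = "quoted string") -> Token:
        tok = self.lex.advance()
        if tok.kind != "DQSTRING":
            raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                                 expected=what)
        return tok

    @staticmethod
    def _show(tok: Token) -> str:
        if tok.kind == "EOF":
            return "end of input"
        return f"{tok.kind} {tok.value!r}"

    # -- document ---------------------------------------------------------
    def parse_document(self) -> Indicator:
        self.expect_kw("metadata")
        metadata = self._metadata_block()
        term_bindings: list[TermBinding] = []
        if self.at_ident("terminology"):
            self.lex.advance()
            while self.at_ident("term"):
                term_bindings.extend(self._term_set())
        self.expect_kw("archetypes")
        bindings = []
        while self.at_ident("archetype"):
            bindings.append(self._archetype_decl())
        self.expect_kw("logic")
        params: list[ParameterDecl] = []
        defines: list[DefineStatement] = []
        while True:
            if self.at_ident("parameter"):
                params.append(self._parameter_decl())
            elif self.at_ident("define"):
                defines.append(self._define_stmt())
            else:
                break
        tok = self.peek()
        if tok.kind != "EOF":
            raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                                 expected="'parameter', 'define' or end of input")
        return Indicator(metadata=metadata, parameters=params,
                         term_bindings=term_bindings,
                         archetype_bindings=bindings, defines=defines)

    def _metadata_block(self) -> MetadataBlock:
        fields: dict[str, str] = {}
        while self.at_ident(*META_KEYS):
            key = self.lex.advance().value
            self.expect_op(":")
            val = self.expect_string(f"value string for {key!r}")
            if key in fields:
                raise CqiSyntaxError(f"duplicate metadata key {key!r}",
                                     val.span)
            fields[key] = val.value
        if "indicator" not in fields:
            tok = self.peek()
            raise CqiSyntaxError("metadata block lacks 'indicator' name",
                                 tok.span, expected="indicator: \"...\"")
        translations = [t for t in fields.get("translation", "").split("|") if t != ""] \
            if "translation" in fields else []
        time = None
        if fields.get("time"):
            try:
                time = datetime.fromisoformat(fields["time"])
            except ValueError:
                raise CqiSyntaxError(
                    f"invalid metadata time {fields['time']!r}",
                    self.peek().span) from None
        return MetadataBlock(
            indicator_name=fields["indicator"],
            version=fields.get("version", "0.1.0"),
            language=fields.get("language", "en"),
            translations=translations,
            description=fields.get("description", ""),
            status=fields.get("status", "DRAFT"),
            author=fields.get("author", ""),
            time=time,
            email=fields.get("email", ""),
        )

    # -- terminology ------------------------------------------------------
    def _term_set(self) -> list[TermBinding]:
        self.expect_kw("term")
        system_raw = self.expect_string("code-system name").value
        uri = None
        if self.at_ident("uri"):
            self.lex.advance()
            uri = self.expect_string("uri string").value
        system = (self.reg.canonical(system_raw)
                  if self.reg.is_registered(system_raw) else system_raw)
        if uri is None:
            uri = self.reg.uri(system)
        self.expect_op("{")
        out: list[TermBinding] = []
        while self.at_ident("bind"):
            out.append(self._bind_stmt(system, uri))
        self.expect_op("}")
        return out

    def _bind_stmt(self, system: str, uri: Optional[str]) -> TermBinding:
        self.expect_kw("bind")
        local = self.expect_ident("terminology local code").value
        self.expect_op("=")
        self.expect_op("[")
        raw, span = self.lex.raw_until_rbracket()
        codes = self._split_code_list(raw, span)
        source_archetype = None
        if self.at_ident("archetype"):
            self.lex.advance()
            source_archetype = self.expect_string("archetype id").value
        elif system.startswith("openEHR-"):
            source_archetype = system
        self.expect_op(";")
        refs = [TermRef(system=system, code=c, system_uri=uri) for c in codes]
        return TermBinding(local_code=local, refs=refs,
                           source_archetype=source_archetype)

    @staticmethod
    def _split_code_list(raw: str, span: SourceSpan) -> list[str]:
        tokens = raw.split()
        if not tokens:
            raise CqiSyntaxError("empty code list", span, expected="a code")
        codes = []
        expect_code = True
        for tok in tokens:
            if expect_code:
                if tok == "or":
                    raise CqiSyntaxError("misplaced 'or' in code list", span)
                codes.append(tok)
            elif tok != "or":
                raise CqiSyntaxError(
                    f"codes must be separated by 'or' (got {tok!r})", span)
            expect_code = not expect_code
        if expect_code:
            raise CqiSyntaxError("code list ends with 'or'", span)
        return codes

    # -- archetypes -------------------------------------------------------
    def _archetype_decl(self) -> ArchetypeBinding:
        self.expect_kw("archetype")
        alias = self.expect_ident("archetype alias").value
        self.expect_op(":")
        self.expect_kw("name")
        archetype_id = self.expect_string("archetype id").value
        template_id = None
        slot_path = ""
        if self.at_ident("in"):
            self.lex.advance()
            self.expect_kw("template")
            template_id = self.expect_string("template id").value
            if self.at_ident("with") :
                # lookahead: 'with path' vs 'with predicates'
                save_cache = self.lex._cache
                save_pos = self.lex.pos
                self.lex.advance()
                if self.at_ident("path"):
                    self.lex.advance()
                    slot_path = self.expect_string("slot path").value
                else:
                    self.lex._cache = save_cache
                    self.lex.pos = save_pos
        self.expect_kw("elements")
        self.expect_op("{")
        elements = []
        while self.peek().kind == "IDENT" and not self.at_ident(*RESERVED):
            code = self.lex.advance().value
            self.expect_op("=")
            path = self.expect_string("element path").value
            self.expect_op(";")
            elements.append(ElementBinding(element_code=code,
                                           element_path=path))
        self.expect_op("}")
        predicates: list[Expr] = []
        if self.at_ident("with"):
            self.lex.advance()
            self.expect_kw("predicates")
            self.expect_op("{")
            while not (self.peek().kind == "OP" and self.peek().value == "}"):
                predicates.append(self.parse_expr())
                self.expect_op(";")
            self.expect_op("}")
        return ArchetypeBinding(alias=alias, archetype_id=archetype_id,
                                template_id=template_id, slot_path=slot_path,
                                elements=elements, predicates=predicates)

    # -- logic ------------------------------------------------------------
    def _parameter_decl(self) -> ParameterDecl:
        self.expect_kw("parameter")
        name = self.expect_ident("parameter name").value
        self.expect_op(":")
        tok = self.expect_ident("parameter type")
        if tok.value == "Interval":
            self.expect_op("<")
            self.expect_kw("DateTime")
            self.expect_op(">")
            ptype = "Interval<DateTime>"
        elif tok.value in PARAM_TYPE_IDENTS:
            ptype = tok.value
        else:
            raise CqiSyntaxError(f"unknown parameter type {tok.value!r}",
                                 tok.span,
                                 expected="Interval<DateTime>, DateTime, "
                                          "Integer, Decimal, String or Code")
        default = None
        if self.at_ident("default"):
            self.lex.advance()
            default = self.parse_expr()
        return ParameterDecl(name=name, param_type=ptype,
                             default_value=default)

    def _define_stmt(self) -> DefineStatement:
        self.expect_kw("define")
        name = self.expect_string("define name").value
        self.expect_op(":")
        body = self.parse_expr()
        return DefineStatement(name=name, body=body)

    # -- expressions ------------------------------------------------------
    def parse_expr(self) -> Expr:
        return self._or_expr()

    def _or_expr(self) -> Expr:
        left = self._and_expr()
        while self.at_ident("or"):
            span = self.lex.advance().span
            right = self._and_expr()
            left = Binary(op="or", left=left, right=right, span=span)
        return left

    def _and_expr(self) -> Expr:
        left = self._not_expr()
        while self.at_ident("and"):
            span = self.lex.advance().span
            right = self._not_expr()
            left = Binary(op="and", left=left, right=right, span=span)
        return left

    def _not_expr(self) -> Expr:
        if self.at_ident("not"):
            span = self.lex.advance().span
            return Not(operand=self._not_expr(), span=span)
        return self._cmp_expr()

    def _cmp_expr(self) -> Expr:
        left = self._set_expr()
        tok = self.peek()
        if tok.kind == "OP" and tok.value in CMP_OPS:
            self.lex.advance()
            right = self._set_expr()
            return Binary(op=tok.value, left=left, right=right, span=tok.span)
        if tok.kind == "IDENT" and tok.value == "during":
            self.lex.advance()
            interval = self._set_expr()
            return During(operand=left, interval=interval, span=tok.span)
        return left

    def _set_expr(self) -> Expr:
        left = self._add_expr()
        while self.at_ident("union", "intersect", "except"):
            tok = self.lex.advance()
            right = self._add_expr()
            left = SetOp(op=tok.value, left=left, right=right, span=tok.span)
        return left

    def _add_expr(self) -> Expr:
        left = self._mul_expr()
        while True:
            tok = self.peek()
            if tok.kind != "OP" or tok.value not in ("+", "-"):
                return left
            self.lex.advance()
            sign = 1 if tok.value == "+" else -1
            nxt = self.peek()
            if nxt.kind == "NUMBER" and "." not in nxt.value:
                self.lex.advance()
                unit_tok = self.peek()
                if unit_tok.kind == "IDENT" and unit_tok.value in TIME_UNITS:
                    self.lex.advance()
                    left = TimeShift(base=left, amount=sign * int(nxt.value),
                                     unit=unit_tok.value, span=tok.span)
                    continue
                rhs: Expr = Literal(value=int(nxt.value),
                                    value_type="Integer", span=nxt.span)
                rhs = self._mul_tail(rhs)
            else:
                rhs = self._mul_expr()
            left = Binary(op=tok.value, left=left, right=rhs, span=tok.span)

    def _mul_expr(self) -> Expr:
        return self._mul_tail(self._unary())

    def _mul_tail(self, left: Expr) -> Expr:
        while True:
            tok = self.peek()
            if tok.kind == "OP" and tok.value in ("*", "/"):
                self.lex.advance()
                right = self._unary()
                left = Binary(op=tok.value, left=left, right=right,
                              span=tok.span)
            else:
                return left

    def _unary(self) -> Expr:
        tok = self.peek()
        if tok.kind == "OP" and tok.value == "-":
            self.lex.advance()
            operand = self._unary()
            if isinstance(operand, Literal) and operand.value_type in (
                    "Integer", "Decimal"):
                return Literal(value=-operand.value,
                               value_type=operand.value_type, span=tok.span)
            raise CqiSyntaxError("unary minus applies to numeric literals "
                                 "only", tok.span)
        if tok.kind == "IDENT" and tok.value in ("start", "end"):
            self.lex.advance()
            self.expect_kw("of")
            operand = self._unary()
            cls = Start if tok.value == "start" else End
            return cls(operand=operand, span=tok.span)
        if tok.kind == "IDENT" and tok.value == "exists":
            self.lex.advance()
            self.expect_op("(")
            inner = self._query()
            self.expect_op(")")
            return Exists(operand=inner, span=tok.span)
        return self._postfix()

    def _postfix(self) -> Expr:
        expr = self._query()
        while True:
            tok = self.peek()
            if tok.kind == "OP" and tok.value == ".":
                self.lex.advance()
                code = self.expect_ident("element code").value
                expr = Projection(source=expr, element_code=code,
                                  span=tok.span)
            else:
                return expr

    def _query(self) -> Expr:
        source = self._primary()
        if self.at_ident("where"):
            span = self.lex.advance().span
            condition = self.parse_expr()
            return Filter(source=source, condition=condition, span=span)
        return source

    def _sort_key(self) -> str:
        if self.at_ident("sort"):
            self.lex.advance()
            self.expect_kw("by")
            tok = self.lex.advance()
            if tok.kind != "IDENT":
                raise CqiSyntaxError(f"unexpected {self._show(tok)}",
                                     tok.span,
                                     expected="element code or entry_time")
            return tok.value
        return "entry_time"

    def _primary(self) -> Expr:
        tok = self.peek()

        if tok.kind == "OP" and tok.value == "(":
            self.lex.advance()
            inner = self.parse_expr()
            self.expect_op(")")
            return inner

        if tok.kind == "OP" and tok.value == "[":
            return self._retrieve()

        if tok.kind == "DQSTRING":
            self.lex.advance()
            return DefineRef(name=tok.value, span=tok.span)
        if tok.kind == "SQSTRING":
            self.lex.advance()
            return Literal(value=tok.value, value_type="String",
                           span=tok.span)
        if tok.kind == "DATETIME":
            self.lex.advance()
            return Literal(value=tok.value, value_type="DateTime",
                           span=tok.span)
        if tok.kind == "NUMBER":
            self.lex.advance()
            if "." in tok.value:
                return Literal(value=float(tok.value), value_type="Decimal",
                               span=tok.span)
            return Literal(value=int(tok.value), value_type="Integer",
                           span=tok.span)

        if tok.kind == "IDENT":
            word = tok.value
            if word == "true" or word == "false":
                self.lex.advance()
                return Literal(value=(word == "true"), value_type="Boolean",
                               span=tok.span)
            if word == "null":
                self.lex.advance()
                return Literal(value=None, value_type="Null", span=tok.span)
            if word == "entry_time":
                self.lex.advance()
                return EntryTimeRef(span=tok.span)
            if word == "Count":
                self.lex.advance()
                self.expect_op("(")
                inner = self._query()
                self.expect_op(")")
                return Count(operand=inner, span=tok.span)
            if word in ("First", "Last"):
                self.lex.advance()
                self.expect_op("(")
                inner = self._query()
                key = self._sort_key()
                self.expect_op(")")
                cls = FirstByTime if word == "First" else LastByTime
                return cls(source=inner, key=key, span=tok.span)
            if word == "AgeInYearsAt":
                self.lex.advance()
                self.expect_op("(")
                birth = self.parse_expr()
                self.expect_op(",")
                at = self.parse_expr()
                self.expect_op(")")
                return AgeInYearsAt(birth=birth, at=at, span=tok.span)
            if word == "Interval":
                self.lex.advance()
                open_tok = self.lex.advance()
                if open_tok.kind != "OP" or open_tok.value not in ("[", "("):
                    raise CqiSyntaxError(
                        f"unexpected {self._show(open_tok)}", open_tok.span,
                        expected="'[' or '('")
                low = self.parse_expr()
                self.expect_op(",")
                high = self.parse_expr()
                close_tok = self.lex.advance()
                if close_tok.kind != "OP" or close_tok.value not in (")", "]"):
                    raise CqiSyntaxError(
                        f"unexpected {self._show(close_tok)}",
                        close_tok.span, expected="']' or ')'")
                return IntervalLit(low=low, high=high,
                                   low_closed=open_tok.value == "[",
                                   high_closed=close_tok.value == "]",
                                   span=tok.span)
            if word in RESERVED:
                raise CqiSyntaxError(f"unexpected keyword {word!r}", tok.span,
                                     expected="an expression")
            self.lex.advance()
            nxt = self.peek()
            if nxt.kind == "OP" and nxt.value == "::":
                return self._shorthand_tail(word, tok.span)
            return NameRef(name=word, span=tok.span)

        raise CqiSyntaxError(f"unexpected {self._show(tok)}", tok.span,
                             expected="an expression")

    def _shorthand_tail(self, system_alias: str, span: SourceSpan) -> TermRef:
        self.expect_op("::")
        self.expect_op("[")
        raw, raw_span = self.lex.raw_until_rbracket()
        code = raw.strip()
        if not code or " " in code:
            raise CqiSyntaxError(f"malformed shorthand code {raw!r}",
                                 raw_span)
        try:
            ref = parse_term_shorthand(f"{system_alias}::[{code}]", self.reg)
        except ShorthandError as exc:
            raise CqiSyntaxError(str(exc), span) from None
        return TermRef(system=ref.system, code=ref.code,
                       system_uri=ref.system_uri, span=span)

    def _retrieve(self) -> Expr:
        open_tok = self.expect_op("[")
        alias = self.expect_ident("archetype alias").value
        term: Union[str, TermRef, None] = None
        tok = self.peek()
        if tok.kind == "OP" and tok.value == ":":
            self.lex.advance()
            t = self.expect_ident("terminology code or SYSTEM::[CODE]")
            nxt = self.peek()
            if nxt.kind == "OP" and nxt.value == "::":
                term = self._shorthand_tail(t.value, t.span)
            else:
                term = t.value
        self.expect_op("]")
        return Retrieve(alias=alias, term=term, span=open_tok.span)


def parse_indicator(text: str,
                    registry: Optional[CodeSystemRegistry] = None) -> Indicator:
    """Parse indicator source text into an :class:`~cqi.model.Indicator`.

    Raises :class:`CqiSyntaxError` (with source position and expected-token
    hint) on malformed input.  Structural validity beyond syntax is the job
    of :func:`~cqi.model.validate_indicator`.
    """
    return _Parser(text, registry or default_registry()).parse_document()


def parse_expression(text: str,
                     registry: Optional[CodeSystemRegistry] = None) -> Expr:
    """Parse a standalone expression (used by the XML reader)."""
    p = _Parser(text, registry or default_registry())
    expr = p.parse_expr()
    tok = p.peek()
    if tok.kind != "EOF":
        raise CqiSyntaxError(f"unexpected {_Parser._show(tok)} after "
                             "expression", tok.span)
    return expr


# ---------------------------------------------------------------------------
# Canonical text serializer
# ---------------------------------------------------------------------------

_BIN_PREC = {"or": 1, "and": 2, "=": 4, "!=": 4, "<": 4, "<=": 4, ">": 4,
             ">=": 4, "+": 6, "-": 6, "*": 7, "/": 7}


def serialize_expression(expr: Expr,
                         registry: Optional[CodeSystemRegistry] = None) -> str:
    """Render an expression in canonical form; reparsing yields an equal
    AST (spans aside)."""
    return _print_expr(expr, 0, registry or default_registry())


def _print_expr(expr: Expr, min_prec: int, reg: CodeSystemRegistry) -> str:
    s, p = _emit(expr, reg)
    return f"({s})" if p < min_prec else s


def _emit(expr: Expr, reg: CodeSystemRegistry) -> tuple[str, int]:
    if isinstance(expr, Literal):
        return _emit_literal(expr), 10
    if isinstance(expr, NameRef):
        return expr.name, 10
    if isinstance(expr, EntryTimeRef):
        return "entry_time", 10
    if isinstance(expr, DefineRef):
        return f'"{escape_string(expr.name)}"', 10
    if isinstance(expr, TermRef):
        return f"{reg.preferred_alias(expr.system)}::[{expr.code}]", 10
    if isinstance(expr, Retrieve):
        if expr.term is None:
            return f"[{expr.alias}]", 10
        term = (expr.term if isinstance(expr.term, str)
                else _emit(expr.term, reg)[0])
        return f"[{expr.alias} : {term}]", 10
    if isinstance(expr, Projection):
        return f"{_print_expr(expr.source, 9, reg)}.{expr.element_code}", 9
    if isinstance(expr, Filter):
        return (f"{_print_expr(expr.source, 9, reg)} where "
                f"{_print_expr(expr.condition, 1, reg)}"), 0
    if isinstance(expr, Exists):
        return f"exists({_print_expr(expr.operand, 0, reg)})", 10
    if isinstance(expr, Count):
        return f"Count({_print_expr(expr.operand, 0, reg)})", 10
    if isinstance(expr, FirstByTime):
        return (f"First({_print_expr(expr.source, 0, reg)} "
                f"sort by {expr.key})"), 10
    if isinstance(expr, LastByTime):
        return (f"Last({_print_expr(expr.source, 0, reg)} "
                f"sort by {expr.key})"), 10
    if isinstance(expr, Not):
        return f"not {_print_expr(expr.operand, 3, reg)}", 3
    if isinstance(expr, Binary):
        p = _BIN_PREC[expr.op]
        left_min = 5 if p == 4 else p
        right_min = 5 if p == 4 else p + 1
        return (f"{_print_expr(expr.left, left_min, reg)} {expr.op} "
                f"{_print_expr(expr.right, right_min, reg)}"), p
    if isinstance(expr, During):
        return (f"{_print_expr(expr.operand, 5, reg)} during "
                f"{_print_expr(expr.interval, 5, reg)}"), 4
    if isinstance(expr, SetOp):
        return (f"{_print_expr(expr.left, 5, reg)} {expr.op} "
                f"{_print_expr(expr.right, 6, reg)}"), 5
    if isinstance(expr, TimeShift):
        sign = "+" if expr.amount >= 0 else "-"
        return (f"{_print_expr(expr.base, 6, reg)} {sign} "
                f"{abs(expr.amount)} {expr.unit}"), 6
    if isinstance(expr, Start):
        return f"start of {_print_expr(expr.operand, 8, reg)}", 8
    if isinstance(expr, End):
        return f"end of {_print_expr(expr.operand, 8, reg)}", 8
    if isinstance(expr, IntervalLit):
        lo = "[" if expr.low_closed else "("
        hi = "]" if expr.high_closed else ")"
        return (f"Interval{lo}{_print_expr(expr.low, 0, reg)}, "
                f"{_print_expr(expr.high, 0, reg)}{hi}"), 10
    if isinstance(expr, AgeInYearsAt):
        return (f"AgeInYearsAt({_print_expr(expr.birth, 0, reg)}, "
                f"{_print_expr(expr.at, 0, reg)})"), 10
    raise TypeError(f"cannot serialize {type(expr).__name__}")


def _emit_literal(lit: Literal) -> str:
    if lit.value_type == "Null":
        return "null"
    if lit.value_type == "Boolean":
        return "true" if lit.value else "false"
    if lit.value_type == "Integer":
        return str(lit.value)
    if lit.value_type == "Decimal":
        return repr(float(lit.value))
    if lit.value_type == "String":
        return f"'{escape_sq(lit.value)}'"
    if lit.value_type == "DateTime":
        return "@" + lit.value.isoformat()
    raise TypeError(f"unknown literal type {lit.value_type!r}")


def serialize_text(ind: Indicator,
                   registry: Optional[CodeSystemRegistry] = None) -> str:
    """Serialize a valid indicator to canonical source text.

    ``parse_indicator(serialize_text(ind))`` is field-identical to ``ind``.
    Raises :class:`~cqi.model.UnvalidatedIndicatorError` on invalid input.
    """
    require_valid(ind)
    reg = registry or default_registry()
    md = ind.metadata
    out: list[str] = ["metadata"]

    def meta(key: str, value: str) -> None:
        out.append(f'    {key}: "{escape_string(value)}"')

    meta("indicator", md.indicator_name)
    meta("version", md.version)
    meta("language", md.language)
    if md.translations:
        meta("translation", "|".join(md.translations))
    if md.description:
        meta("description", md.description)
    meta("status", md.status)
    if md.author:
        meta("author", md.author)
    if md.time is not None:
        meta("time", md.time.isoformat())
    if md.email:
        meta("email", md.email)
    out.append("")

    if ind.term_bindings:
        out.append("terminology")
        prev_key = None
        for tb in ind.term_bindings:
            system = tb.refs[0].system
            uri = tb.refs[0].system_uri
            key = (system, uri)
            if key != prev_key:
                if prev_key is not None:
                    out.append("    }")
                head = f'    term "{escape_string(system)}"'
                if uri:
                    head += f' uri "{escape_string(uri)}"'
                out.append(head + " {")
                prev_key = key
            codes = " or ".join(r.code for r in tb.refs)
            line = f"        bind {tb.local_code} = [{codes}]"
            if tb.source_archetype and tb.source_archetype != system:
                line += f' archetype "{escape_string(tb.source_archetype)}"'
            out.append(line + ";")
        out.append("    }")
        out.append("")

    out.append("archetypes")
    for ab in ind.archetype_bindings:
        out.append(f'    archetype {ab.alias}: '
                   f'name "{escape_string(ab.archetype_id)}"')
        if ab.template_id is not None:
            out.append(f'        in template "{escape_string(ab.template_id)}"'
                       f' with path "{escape_string(ab.slot_path)}"')
        out.append("        elements {")
        for e in ab.elements:
            out.append(f'            {e.element_code} = '
                       f'"{escape_string(e.element_path)}";')
        out.append("        }")
        if ab.predicates:
            out.append("        with predicates {")
            for pred in ab.predicates:
                out.append(f"            {_print_expr(pred, 0, reg)};")
            out.append("        }")
    out.append("")

    out.append("logic")
    for p in ind.parameters:
        line = f"    parameter {p.name}: {p.param_type}"
        if p.default_value is not None:
            line += f" default {_print_expr(p.default_value, 0, reg)}"
        out.append(line)
    for d in ind.defines:
        out.append("")
        out.append(f'    define "{escape_string(d.name)}":')
        out.append(f"        {_print_expr(d.body, 0, reg)}")
    out.append("")
    return "\n".join(out)
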