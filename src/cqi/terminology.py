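"""Terminology binding: code systems, value sets and membership tests.

An indicator names terms through local codes; each local code binds to one
or more terms (``TermRef``) with disjunctive semantics — a coded value
satisfies the binding when it matches *any* bound term.  Terms come either
from external code systems (ICD-10, SNOMED-CT, ...) or from an archetype's
internal ``at``-code vocabulary, in which case the archetype id plays the
role of the code system.

Membership is extensional: no subsumption, no hierarchy, no terminology
server.  Codes are opaque tokens compared exactly and case-sensitively
(clinical sources mix dialects such as ``N185`` and ``N18.6``; both are
legal and distinct).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

from .model import TermBinding, TermRef

__all__ = [
    "CodeSystemRegistry", "ResolvedValueSet", "default_registry",
    "expand_at_range", "resolve_binding", "code_matches",
    "load_codesystem_file", "RangeError", "UnknownSystemError",
    "FormatError",
]

AT_RANGE_RE = re.compile(r"^at(\d{4})-at(\d{4})$")
AT_SINGLE_RE = re.compile(r"^at\d{4}$")


class RangeError(ValueError):
    """Malformed or reversed at-code range."""


class UnknownSystemError(KeyError):
    """Code system neither registered nor an archetype id."""


class FormatError(ValueError):
    """Bad row in a code-system registry file."""


@dataclass
class _SystemEntry:
    canonical: str
    uri: str | None = None
    aliases: list[str] = field(default_factory=list)


class CodeSystemRegistry:
    """Maps code-system aliases (``ICD10``) to canonical names (``ICD-10``).

    Lookup is case-insensitive over both aliases and canonical names;
    registration rejects duplicate aliases.
    """

    def __init__(self) -> None:
        self._by_alias: dict[str, _SystemEntry] = {}
        self._entries: list[_SystemEntry] = []

    def register(self, canonical: str, *, uri: str | None = None,
                 aliases: tuple[str, ...] = ()) -> None:
        entry = self._by_canonical(canonical)
        if entry is None:
            entry = _SystemEntry(canonical, uri)
            self._entries.append(entry)
            self._add_alias(canonical, entry)
        elif uri and not entry.uri:
            entry.uri = uri
        for a in aliases:
            self._add_alias(a, entry)

    def _add_alias(self, alias: str, entry: _SystemEntry) -> None:
        key = alias.lower()
        existing = self._by_alias.get(key)
        if existing is not None and existing is not entry:
            raise FormatError(f"alias {alias!r} already registered "
                              f"for {existing.canonical!r}")
        if existing is None:
            self._by_alias[key] = entry
            entry.aliases.append(alias)

    def _by_canonical(self, name: str) -> _SystemEntry | None:
        e = self._by_alias.get(name.lower())
        return e if e is not None and e.canonical == name else None

    def is_registered(self, name: str) -> bool:
        return name.lower() in self._by_alias

    def canonical(self, name: str) -> str:
        """Canonical system name for an alias or canonical name.

        Archetype ids (``openEHR-...``) act as their own system and pass
        through unchanged; anything else must be registered.
        """
        e = self._by_alias.get(name.lower())
        if e is not None:
            return e.canonical
        if name.startswith("openEHR-"):
            return name
        raise UnknownSystemError(name)

    def uri(self, name: str) -> str | None:
        e = self._by_alias.get(name.lower())
        return e.uri if e else None

    def preferred_alias(self, canonical: str) -> str:
        """Shortest registered alias, used by the ``SYS::[CODE]`` shorthand
        serializer; falls back to the canonical name itself."""
        e = self._by_alias.get(canonical.lower())
        if e is None:
            return canonical
        short = [a for a in e.aliases if a != e.canonical]
        return min(short, key=len) if short else e.canonical

    def systems(self) -> list[str]:
        return [e.canonical for e in self._entries]


def default_registry() -> CodeSystemRegistry:
    """Registry preloaded with the code systems an indicator author can
    abbreviate out of the box.  ICD-10 is the built-in default."""
    reg = CodeSystemRegistry()
    reg.register("ICD-10", uri="http://hl7.org/fhir/sid/icd-10",
                 aliases=("ICD10",))
    reg.register("ICD-9", uri="http://hl7.org/fhir/sid/icd-9-cm",
                 aliases=("ICD9",))
    reg.register("SNOMED-CT", uri="http://snomed.info/sct",
                 aliases=("SNOMEDCT", "SNOMED"))
    reg.register("LOINC", uri="http://loinc.org")
    return reg


def load_codesystem_file(path) -> CodeSystemRegistry:
    """Load a registry file (CSV, header ``alias,canonical,uri``) on top of
    the built-in defaults.  Duplicate aliases raise :class:`FormatError`
    with the offending row number."""
    reg = default_registry()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return reg
        if [h.strip().lower() for h in header[:3]] != ["alias", "canonical", "uri"]:
            raise FormatError(f"{path}: row 1: expected header alias,canonical,uri")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: row {lineno}: need alias and canonical")
            alias, canonical = row[0].strip(), row[1].strip()
            uri = row[2].strip() if len(row) > 2 and row[2].strip() else None
            if not alias or not canonical:
                raise FormatError(f"{path}: row {lineno}: empty alias or canonical")
            try:
                reg.register(canonical, uri=uri, aliases=(alias,))
            except FormatError as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from None
    return reg


def expand_at_range(token: str) -> list[str]:
    """Expand ``at0014-at0022`` to the inclusive, zero-padded code list;
    a single at-code expands to itself."""
    if AT_SINGLE_RE.match(token):
        return [token]
    m = AT_RANGE_RE.match(token)
    if not m:
        raise RangeError(f"malformed at-code range {token!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo > hi:
        raise RangeError(f"reversed at-code range {token!r}")
    return [f"at{i:04d}" for i in range(lo, hi + 1)]


@dataclass(frozen=True)
class ResolvedValueSet:
    """Extensional expansion of one terminology binding.

    ``members`` holds every (system, code) pair the local code may stand
    for; a value matches when it equals any member ("any of" semantics).
    """

    local_code: str
    members: frozenset[TermRef]

    def __contains__(self, value) -> bool:
        system, code = value
        return any(r.system == system and r.code == code for r in self.members)


def resolve_binding(tb: TermBinding, reg: CodeSystemRegistry) -> ResolvedValueSet:
    """Expand a terminology binding into its full member set.

    Canonicalizes system names through the registry, expands at-code
    ranges, and stamps archetype-internal members with their source
    archetype as the system.  Monotone in the binding's ref list.
    """
    members: set[TermRef] = set()
    for ref in tb.refs:
        if AT_RANGE_RE.match(ref.code) or AT_SINGLE_RE.match(ref.code):
            system = tb.source_archetype or ref.system
            if not system:
                raise UnknownSystemError(
                    f"at-code {ref.code!r} in {tb.local_code} has no source archetype")
            for code in expand_at_range(ref.code):
                members.add(TermRef(system=system, code=code))
        else:
            system = reg.canonical(ref.system)
            members.add(TermRef(system=system, code=ref.code,
                                system_uri=ref.system_uri or reg.uri(system)))
    return ResolvedValueSet(local_code=tb.local_code, members=frozenset(members))


def code_matches(value: tuple[str, str], vs: ResolvedValueSet,
                 reg: CodeSystemRegistry | None = None) -> bool:
    """True iff the coded value's exact (system, code) pair is a member.

    System comparison goes through canonical names (so data recorded under
    an alias still matches); code comparison is exact and case-sensitive —
    no prefix or hierarchy matching.
    """
    system, code = value
    if not system or not code:
        return False
    if reg is not None and reg.is_registered(system):
        system = reg.canonical(system)
    return (system, code) in vs
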