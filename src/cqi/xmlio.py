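"""XML interchange for indicator artifacts.

Network transmission of indicators uses an XML representation, one
indicator per document, validated against the shipped ``cqi-1.0.xsd``.
Declaration blocks map onto structured elements; expression logic travels
as canonical indicator-language text inside ``predicate``, ``default`` and
``define`` elements and is reparsed on load, so the XML round trip is the
identity on valid artifacts.
"""

from __future__ import annotations

from datetime import datetime
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

from lxml import etree

from .model import (ArchetypeBinding, DefineStatement, ElementBinding,
                    Indicator, MetadataBlock, ParameterDecl, TermBinding,
                    TermRef, require_valid)
from .parser import parse_expression, serialize_expression
from .terminology import CodeSystemRegistry, default_registry

__all__ = ["serialize_xml", "parse_xml", "SchemaError"]


class SchemaError(ValueError):
    """Document rejected by the interchange schema; carries the element
    path of the first violation."""

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{message}" + (f" at {path}" if path else ""))
        self.path = path


@lru_cache(maxsize=1)
def _schema() -> etree.XMLSchema:
    data = (resources.files("cqi") / "schemas" / "cqi-1.0.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(data))


def serialize_xml(ind: Indicator,
                  registry: Optional[CodeSystemRegistry] = None) -> str:
    """Serialize a valid indicator to an XML document string."""
    require_valid(ind)
    reg = registry or default_registry()
    md = ind.metadata
    root = etree.Element("indicator", schemaVersion="1.0")

    meta = etree.SubElement(root, "metadata")
    etree.SubElement(meta, "name").text = md.indicator_name
    etree.SubElement(meta, "version").text = md.version
    etree.SubElement(meta, "language").text = md.language
    for t in md.translations:
        etree.SubElement(meta, "translation").text = t
    etree.SubElement(meta, "description").text = md.description
    etree.SubElement(meta, "status").text = md.status
    etree.SubElement(meta, "author").text = md.author
    if md.time is not None:
        etree.SubElement(meta, "time").text = md.time.isoformat()
    etree.SubElement(meta, "email").text = md.email

    if ind.term_bindings:
        term = etree.SubElement(root, "terminology")
        for tb in ind.term_bindings:
            b = etree.SubElement(term, "binding", localCode=tb.local_code)
            if tb.source_archetype:
                b.set("sourceArchetype", tb.source_archetype)
            for r in tb.refs:
                el = etree.SubElement(b, "term", system=r.system,
                                      code=r.code)
                if r.system_uri:
                    el.set("uri", r.system_uri)

    arch = etree.SubElement(root, "archetypes")
    for ab in ind.archetype_bindings:
        b = etree.SubElement(arch, "binding", alias=ab.alias,
                             archetypeId=ab.archetype_id)
        if ab.template_id is not None:
            b.set("templateId", ab.template_id)
            b.set("slotPath", ab.slot_path)
        for e in ab.elements:
            etree.SubElement(b, "element", code=e.element_code,
                             path=e.element_path)
        for pred in ab.predicates:
            etree.SubElement(b, "predicate").text = serialize_expression(
                pred, reg)

    logic = etree.SubElement(root, "logic")
    for p in ind.parameters:
        el = etree.SubElement(logic, "parameter", name=p.name,
                              type=p.param_type)
        if p.default_value is not None:
            etree.SubElement(el, "default").text = serialize_expression(
                p.default_value, reg)
    for d in ind.defines:
        el = etree.SubElement(logic, "define", name=d.name)
        el.text = serialize_expression(d.body, reg)

    return etree.tostring(root, pretty_print=True, encoding="unicode",
                          xml_declaration=False)


def _text(parent, tag: str, default: str = "") -> str:
    el = parent.find(tag)
    if el is None:
        return default
    return el.text or ""


def parse_xml(doc: Union[str, bytes],
              registry: Optional[CodeSystemRegistry] = None) -> Indicator:
    """Parse and schema-validate an XML indicator document.

    Raises :class:`SchemaError` (with the element path of the violation)
    when the document does not conform to ``cqi-1.0.xsd``.
    """
    reg = registry or default_registry()
    if isinstance(doc, str):
        doc = doc.encode("utf-8")
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"not well-formed XML: {exc}") from None
    schema = _schema()
    if not schema.validate(root):
        err = schema.error_log[0]
        raise SchemaError(err.message, path=err.path or "")

    meta_el = root.find("metadata")
    time_text = _text(meta_el, "time")
    metadata = MetadataBlock(
        indicator_name=_text(meta_el, "name"),
        version=_text(meta_el, "version"),
        language=_text(meta_el, "language"),
        translations=[el.text or "" for el in meta_el.findall("translation")],
        description=_text(meta_el, "description"),
        status=_text(meta_el, "status"),
        author=_text(meta_el, "author"),
        time=datetime.fromisoformat(time_text) if time_text else None,
        email=_text(meta_el, "email"),
    )

    term_bindings = []
    term_el = root.find("terminology")
    if term_el is not None:
        for b in term_el.findall("binding"):
            refs = [TermRef(system=t.get("system"), code=t.get("code"),
                            system_uri=t.get("uri"))
                    for t in b.findall("term")]
            term_bindings.append(TermBinding(
                local_code=b.get("localCode"), refs=refs,
                source_archetype=b.get("sourceArchetype")))

    bindings = []
    for b in root.find("archetypes").findall("binding"):
        template_id = b.get("templateId")
        bindings.append(ArchetypeBinding(
            alias=b.get("alias"),
            archetype_id=b.get("archetypeId"),
            template_id=template_id,
            slot_path=b.get("slotPath", "") if template_id is not None else "",
            elements=[ElementBinding(element_code=e.get("code"),
                                     element_path=e.get("path"))
                      for e in b.findall("element")],
            predicates=[parse_expression(p.text or "", reg)
                        for p in b.findall("predicate")],
        ))

    logic_el = root.find("logic")
    params = []
    for p in logic_el.findall("parameter"):
        default_el = p.find("default")
        params.append(ParameterDecl(
            name=p.get("name"), param_type=p.get("type"),
            default_value=(parse_expression(default_el.text or "", reg)
                           if default_el is not None else None)))
    defines = [DefineStatement(name=d.get("name"),
                               body=parse_expression(d.text or "", reg))
               for d in logic_el.findall("define")]

    return Indicator(metadata=metadata, parameters=params,
                     term_bindings=term_bindings,
                     archetype_bindings=bindings, defines=defines)
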