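"""cqi: configurable clinical quality indicators over openEHR-shaped data.

A small toolchain for authoring and computing clinical quality indicators:
a CQL-style expression language extended with openEHR archetype binding,
terminology binding and management metadata; a parser with canonical text
and XML serializers; an evaluation engine producing proportion and count
measures over a flat archetype-mapped repository; and a deterministic
synthetic-cohort generator for testing.
"""

from importlib import resources

from .model import (  # noqa: F401
    ArchetypeBinding, DefineStatement, ElementBinding, Indicator,
    MetadataBlock, ParameterDecl, Status, TermBinding, TermRef,
    ValidationReport, list_required_archetypes, topological_define_order,
    validate_indicator,
)
from .parser import (  # noqa: F401
    CqiSyntaxError, parse_expression, parse_indicator, parse_term_shorthand,
    serialize_text,
)
from .xmlio import parse_xml, serialize_xml  # noqa: F401
from .terminology import (  # noqa: F401
    CodeSystemRegistry, ResolvedValueSet, code_matches, default_registry,
    expand_at_range, load_codesystem_file, resolve_binding,
)
from .cdr import Repository, load_fixture, schema_from_indicator  # noqa: F401
from .engine import (  # noqa: F401
    MeasureResult, evaluate_expression, evaluate_for_patient,
    evaluate_population,
)

__version__ = "0.1.0"

#: Shipped worked-example indicators.
BP_FIXTURE = "controlling_high_blood_pressure.cqi"
APACHE_FIXTURE = "apache_icu_count.cqi"


def fixture_text(name: str) -> str:
    """Source text of a shipped ``.cqi`` fixture."""
    return (resources.files(__name__) / "fixtures" / name).read_text(
        encoding="utf-8")


def load_fixture_indicator(name: str) -> Indicator:
    """Parse a shipped fixture into an :class:`Indicator`."""
    return parse_indicator(fixture_text(name))
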