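"""Object-model validation, reachability and define ordering."""

import copy

import pytest

from cqi.model import (ArchetypeBinding, CyclicDefinesError, DefineRef,
                       DefineStatement, ElementBinding, Indicator, Literal,
                       MetadataBlock, Retrieve, TermBinding, TermRef,
                       UnvalidatedIndicatorError, list_required_archetypes,
                       topological_define_order, validate_indicator)


def _codes(report):
    return {i.code for i in report}


def _minimal(**kw):
    base = dict(
        metadata=MetadataBlock(indicator_name="T", status="DRAFT"),
        archetype_bindings=[ArchetypeBinding(
            alias="AB0001", archetype_id="openEHR-EHR-OBSERVATION.x.v1",
            elements=[ElementBinding("E0001", "/data/value")])],
        defines=[
            DefineStatement("InitialPopulation",
                            Literal(True, "Boolean")),
            DefineStatement("Denominator", DefineRef("InitialPopulation")),
            DefineStatement("Numerator", Retrieve(alias="AB0001")),
        ],
    )
    base.update(kw)
    return Indicator(**base)


def test_fixture_indicators_have_no_issues(bp_indicator, apache_indicator):
    assert list(validate_indicator(bp_indicator)) == []
    assert list(validate_indicator(apache_indicator)) == []


def test_validation_is_pure_and_idempotent(bp_indicator):
    snapshot = copy.deepcopy(bp_indicator)
    first = validate_indicator(bp_indicator)
    second = validate_indicator(bp_indicator)
    assert list(first) == list(second)
    assert bp_indicator == snapshot


@pytest.mark.parametrize("mutate, expected_code", [
    (lambda i: setattr(i.metadata, "status", "RETIRED"),
     "META_STATUS_INVALID"),
    (lambda i: setattr(i.metadata, "translations", ["en", ""]),
     "META_TRANSLATION_EMPTY"),
    (lambda i: i.defines.append(
        DefineStatement("Extra", Retrieve(alias="AB9999"))),
     "REF_UNRESOLVED_ALIAS"),
    (lambda i: i.defines.append(
        DefineStatement("Extra", DefineRef("NoSuchDefine"))),
     "REF_UNRESOLVED_DEFINE"),
    (lambda i: i.defines.append(
        DefineStatement("numerator", Literal(True, "Boolean"))),
     "DEFINE_DUPLICATE"),
    (lambda i: i.archetype_bindings.append(ArchetypeBinding(
        alias="AB0001", archetype_id="openEHR-EHR-OBSERVATION.y.v1")),
     "BINDING_ALIAS_DUPLICATE"),
    (lambda i: i.archetype_bindings[0].elements.append(
        ElementBinding("E0002", "no-leading-slash")),
     "ELEMENT_PATH_INVALID"),
    (lambda i: setattr(i.archetype_bindings[0], "slot_path", "/content"),
     "BINDING_SLOT_WITHOUT_TEMPLATE"),
    (lambda i: i.term_bindings.append(TermBinding(
        "TB0001", refs=[TermRef("openEHR-EHR-OBSERVATION.x.v1",
                                "at0001")])),
     "TERM_ATCODE_NO_ARCHETYPE"),
    (lambda i: i.term_bindings.append(TermBinding("TB0002", refs=[])),
     "TERM_EMPTY_REFS"),
    (lambda i: i.defines.pop(),  # drops Numerator
     "POPULATION_MISSING"),
])
def test_each_broken_invariant_yields_its_code(mutate, expected_code):
    ind = _minimal()
    mutate(ind)
    assert expected_code in _codes(validate_indicator(ind))


def test_deprecated_status_warns_but_stays_valid():
    ind = _minimal()
    ind.metadata.status = "DEPRECATED"
    report = validate_indicator(ind)
    assert report.ok
    assert "META_STATUS_DEPRECATED" in _codes(report)


def test_filter_scope_rejects_foreign_element_codes(bp_indicator):
    # E0501 belongs to the BP binding, not to DIAG
    ind = copy.deepcopy(bp_indicator)
    from cqi.parser import parse_expression
    ind.defines.append(DefineStatement(
        "Broken", parse_expression("exists([DIAG : HTN] where E0501 > 0)")))
    assert "REF_UNRESOLVED_NAME" in _codes(validate_indicator(ind))


class TestRequiredArchetypes:
    def test_bp_fixture_lists_all_referenced_archetypes(self, bp_indicator):
        ids = {a for a, _ in list_required_archetypes(bp_indicator)}
        assert ids == {
            "openEHR-EHR-EVALUATION.problem_diagnosis.v1",
            "openEHR-DEMOGRAPHIC-PERSON.person-patient.v1",
            "openEHR-DEMOGRAPHIC-CLUSTER.person_birth_data_iso.v1",
            "openEHR-EHR-ADMIN_ENTRY.admission.v1",
            "openEHR-EHR-OBSERVATION.imaging_exam.v0",
            "openEHR-EHR-OBSERVATION.blood_pressure.v1",
        }

    def test_apache_fixture_needs_admission_and_score(self,
                                                      apache_indicator):
        ids = {a for a, _ in list_required_archetypes(apache_indicator)}
        assert ids == {"openEHR-EHR-ADMIN_ENTRY.admission.v1",
                       "openEHR-EHR-OBSERVATION.apache_ii.v0"}

    def test_unreferenced_binding_is_excluded(self):
        ind = _minimal()
        ind.archetype_bindings.append(ArchetypeBinding(
            alias="AB0002", archetype_id="openEHR-EHR-OBSERVATION.unused.v1"))
        ids = {a for a, _ in list_required_archetypes(ind)}
        assert "openEHR-EHR-OBSERVATION.unused.v1" not in ids

    def test_requires_a_valid_indicator(self):
        ind = _minimal()
        ind.metadata.status = "RETIRED"
        with pytest.raises(UnvalidatedIndicatorError):
            list_required_archetypes(ind)


class TestDefineOrder:
    def test_dependency_ordered_before_dependent(self, bp_indicator):
        order = topological_define_order(bp_indicator)
        assert order.index("InitialPopulation") < order.index("Denominator")
        assert order.index("MostRecentBP") < order.index("Numerator")

    def test_independent_defines_keep_declaration_order(self):
        ind = _minimal(defines=[
            DefineStatement("A", Literal(1, "Integer")),
            DefineStatement("B", Literal(2, "Integer")),
            DefineStatement("InitialPopulation", Literal(True, "Boolean")),
            DefineStatement("Denominator", Literal(True, "Boolean")),
            DefineStatement("Numerator", Literal(True, "Boolean")),
        ])
        assert topological_define_order(ind)[:2] == ["A", "B"]

    def test_cycle_raises(self):
        ind = _minimal(defines=[
            DefineStatement("A", DefineRef("B")),
            DefineStatement("B", DefineRef("A")),
        ])
        with pytest.raises(CyclicDefinesError):
            topological_define_order(ind)

    def test_order_never_references_a_later_define(self, bp_indicator):
        from cqi.model import DefineRef as DR, walk
        order = topological_define_order(bp_indicator)
        seen = set()
        for name in order:
            body = bp_indicator.find_define(name).body
            for node in walk(body):
                if isinstance(node, DR):
                    assert node.name.lower() in seen
            seen.add(name.lower())
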