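"""Parsing, serialization round-trips and the term shorthand."""

from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cqi
from cqi.model import IntervalLit, Literal, TermRef
from cqi.parser import (CqiSyntaxError, ShorthandError, parse_expression,
                        parse_indicator, parse_term_shorthand,
                        serialize_expression, serialize_text)
from cqi.terminology import RangeError, expand_at_range
from cqi.xmlio import SchemaError, parse_xml, serialize_xml

from _builders import random_indicator


class TestParseIndicator:
    def test_bp_fixture_measurement_period_default(self, bp_indicator):
        (mp,) = [p for p in bp_indicator.parameters
                 if p.name == "MeasurementPeriod"]
        assert mp.param_type == "Interval<DateTime>"
        default = mp.default_value
        assert isinstance(default, IntervalLit)
        assert default.low == Literal(datetime(2016, 1, 1), "DateTime")
        assert default.high == Literal(datetime(2017, 1, 1), "DateTime")
        assert default.low_closed and not default.high_closed

    def test_archetype_id_is_kept_verbatim(self, bp_indicator):
        diag = bp_indicator.binding("DIAG")
        assert diag.archetype_id == "openEHR-EHR-EVALUATION.problem_diagnosis.v1"

    def test_slotted_binding_carries_template_and_path(self, bp_indicator):
        birth = bp_indicator.binding("BIRTH")
        assert birth.template_id == "patient_demographics.t.v1"
        assert birth.slot_path.startswith("/content[")

    def test_translation_field_splits_on_pipe(self, bp_indicator):
        assert bp_indicator.metadata.translations == ["zh-CN", "en"]

    def test_truncated_source_reports_final_position(self, bp_indicator):
        text = serialize_text(bp_indicator)
        cut = text[:text.index("elements {") + len("elements {")]
        with pytest.raises(CqiSyntaxError) as exc:
            parse_indicator(cut)
        assert exc.value.span.line == cut.count("\n") + 1

    def test_error_carries_expected_hint(self):
        with pytest.raises(CqiSyntaxError) as exc:
            parse_indicator("metadata\n  version: \"1\"\n")
        assert exc.value.expected is not None

    def test_datetime_accepts_space_and_t_separator(self):
        a = parse_expression('@2016-01-01T12:30:00')
        b = parse_expression('@"2016-01-01 12:30:00"')
        assert a == b == Literal(datetime(2016, 1, 1, 12, 30), "DateTime")

    def test_comments_are_ignored(self):
        expr = parse_expression("1 + 2 // trailing comment\n + 3")
        assert serialize_expression(expr) == "1 + 2 + 3"


class TestTermShorthand:
    @pytest.mark.parametrize("token, system, code", [
        ("ICD10::[N185]", "ICD-10", "N185"),
        ("ICD10::[I10]", "ICD-10", "I10"),
        ("SNOMEDCT::[38341003]", "SNOMED-CT", "38341003"),
    ])
    def test_alias_resolves_to_canonical_system(self, token, system, code):
        ref = parse_term_shorthand(token)
        assert (ref.system, ref.code) == (system, code)

    @pytest.mark.parametrize("token", [
        "ICD10::N185", "ICD10::[N185", "::[N185]", "ICD10[N185]",
        "NOSUCHSYSTEM::[X1]",
    ])
    def test_malformed_or_unregistered_raises(self, token):
        with pytest.raises(ShorthandError):
            parse_term_shorthand(token)


class TestAtRanges:
    def test_admission_type_range_has_nine_codes(self):
        codes = expand_at_range("at0014-at0022")
        assert codes == [f"at{i:04d}" for i in range(14, 23)]

    def test_single_code_is_singleton(self):
        assert expand_at_range("at0001") == ["at0001"]

    @pytest.mark.parametrize("token", ["at0022-at0014", "at14-at22",
                                       "at0014-", "0014-0022"])
    def test_reversed_or_malformed_raises(self, token):
        with pytest.raises(RangeError):
            expand_at_range(token)

    @settings(derandomize=True, max_examples=60)
    @given(lo=st.integers(0, 9999), span=st.integers(0, 60))
    def test_expansion_size_and_padding(self, lo, span):
        hi = min(lo + span, 9999)
        codes = expand_at_range(f"at{lo:04d}-at{hi:04d}")
        assert len(codes) == hi - lo + 1
        assert all(len(c) == 6 for c in codes)


class TestRoundTrip:
    def test_fixtures_round_trip_text_and_xml(self, bp_indicator,
                                              apache_indicator):
        for ind in (bp_indicator, apache_indicator):
            assert parse_indicator(serialize_text(ind)) == ind
            assert parse_xml(serialize_xml(ind)) == ind

    @pytest.mark.parametrize("seed", range(0, 60))
    def test_random_indicators_round_trip(self, seed):
        ind = random_indicator(seed)
        assert cqi.validate_indicator(ind).ok
        assert parse_indicator(serialize_text(ind)) == ind
        assert parse_xml(serialize_xml(ind)) == ind

    def test_serialization_is_canonical(self, bp_indicator):
        text = serialize_text(bp_indicator)
        assert serialize_text(parse_indicator(text)) == text

    def test_expression_precedence_survives_round_trip(self):
        cases = [
            "a and (b or c)",
            "not (a and b)",
            "(1 + 2) * 3",
            "start of (MeasurementPeriod + 6 months)",
            "start of MeasurementPeriod + 6 months",
            "Last(([AB] where E1 > 0) where E2 < 9 sort by entry_time)",
            "([AB] where E1 = ICD10::[I10]).E1",
        ]
        for text in cases:
            expr = parse_expression(text)
            again = parse_expression(serialize_expression(expr))
            assert again == expr, text


class TestXml:
    def test_unknown_status_is_a_schema_error(self, bp_indicator):
        doc = serialize_xml(bp_indicator).replace(
            "<status>PUBLISHED</status>", "<status>RETIRED</status>")
        with pytest.raises(SchemaError) as exc:
            parse_xml(doc)
        assert "status" in str(exc.value)

    def test_omitted_template_id_loads_as_unset(self, bp_indicator):
        ind = parse_xml(serialize_xml(bp_indicator))
        assert ind.binding("DIAG").template_id is None

    def test_shorthand_system_alias_in_expressions(self):
        ref = parse_expression("ICD10::[N18.6]")
        assert ref == TermRef(system="ICD-10", code="N18.6",
                              system_uri="http://hl7.org/fhir/sid/icd-10")
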