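"""Expression semantics and population evaluation."""

import copy
from datetime import datetime
from fractions import Fraction

import pytest

from cqi.cdr import (Coded, EntryRecord, Quantity, Repository, load_fixture,
                     TimeInterval)
from cqi.engine import (EvalTypeError, EvaluationContext,
                        MissingParameterError, UnknownPatientError,
                        evaluate_expression, evaluate_for_patient,
                        evaluate_population, parse_param_value)
from cqi.model import ParameterDecl
from cqi.parser import parse_expression
from cqi.terminology import default_registry, resolve_binding

BP = "openEHR-EHR-OBSERVATION.blood_pressure.v1"
DIAG = "openEHR-EHR-EVALUATION.problem_diagnosis.v1"
PAT = "openEHR-DEMOGRAPHIC-PERSON.person-patient.v1"
BIRTH = "openEHR-DEMOGRAPHIC-CLUSTER.person_birth_data_iso.v1"
TPL = "patient_demographics.t.v1"
SYS_PATH = "/data[at0001]/events[at0006]/data[at0003]/items[at0004]/value"
DIA_PATH = "/data[at0001]/events[at0006]/data[at0003]/items[at0005]/value"
DIAG_CODE = "/data[at0001]/items[at0002]/value"
DIAG_DATE = "/data[at0001]/items[at0003]/value"
PAT_ID = "/details[at0001]/items[at0003]/value"
BIRTH_DATE = "/items[at0001]/value"


def _ctx(bp_indicator, repo, patient_id="P1"):
    reg = default_registry()
    value_sets = {tb.local_code: resolve_binding(tb, reg)
                  for tb in bp_indicator.term_bindings}
    params = {"MeasurementPeriod": TimeInterval(datetime(2016, 1, 1),
                                                datetime(2017, 1, 1))}
    return EvaluationContext(indicator=bp_indicator, repo=repo,
                             patient_id=patient_id, params=params,
                             value_sets=value_sets, registry=reg)


def _add(repo, archetype, template, pid, t, values):
    repo.add(archetype, template, EntryRecord(
        patient_id=pid, archetype_id=archetype, template_id=template,
        entry_time=t, values=values))


@pytest.fixture()
def empty_repo(bp_schema):
    return Repository(bp_schema)


@pytest.fixture()
def single_patient_repo(bp_schema):
    """Age 40, essential hypertension diagnosed 2015-06-01, one in-period
    blood pressure of 130/80, no exclusions."""
    repo = Repository(bp_schema)
    _add(repo, PAT, None, "P1", datetime(2010, 1, 1), {PAT_ID: "MRN1"})
    _add(repo, BIRTH, TPL, "P1", datetime(2010, 1, 1),
         {BIRTH_DATE: datetime(1976, 1, 1)})
    _add(repo, DIAG, None, "P1", datetime(2015, 6, 1),
         {DIAG_CODE: Coded("ICD-10", "I10"),
          DIAG_DATE: datetime(2015, 6, 1)})
    _add(repo, BP, None, "P1", datetime(2016, 5, 1),
         {SYS_PATH: Quantity(130, "mmHg"), DIA_PATH: Quantity(80, "mmHg")})
    return repo


class TestExpressionSemantics:
    def test_age_in_completed_years(self, bp_indicator, empty_repo):
        ctx = _ctx(bp_indicator, empty_repo)
        expr = parse_expression(
            "AgeInYearsAt(@1931-01-01T00:00:00, @2016-01-01T00:00:00)")
        assert evaluate_expression(expr, ctx) == 85
        expr = parse_expression(
            "AgeInYearsAt(@1931-01-02T00:00:00, @2016-01-01T00:00:00)")
        assert evaluate_expression(expr, ctx) == 84

    def test_exists_over_empty_repository_is_false(self, bp_indicator,
                                                   empty_repo):
        ctx = _ctx(bp_indicator, empty_repo)
        assert evaluate_expression(parse_expression("exists([BP])"),
                                   ctx) is False
        assert evaluate_expression(parse_expression("Count([BP])"), ctx) == 0

    @pytest.mark.parametrize("text, expected", [
        ("1 < null", None),
        ("null = null", None),
        ("true and null", None),
        ("false and null", False),
        ("true or null", True),
        ("null or null", None),
        ("not null", None),
        ("1 / 0", None),
        ("3 + 4 * 2", 11),
        ("@2016-03-15T00:00:00 during MeasurementPeriod", True),
        ("@2017-01-01T00:00:00 during MeasurementPeriod", False),
        ("@2016-01-01T00:00:00 during MeasurementPeriod", True),
        ("start of MeasurementPeriod + 6 months = @2016-07-01T00:00:00",
         True),
        ("end of MeasurementPeriod - 1 years = @2016-01-01T00:00:00", True),
    ])
    def test_three_valued_logic_and_temporal_arithmetic(
            self, bp_indicator, empty_repo, text, expected):
        ctx = _ctx(bp_indicator, empty_repo)
        assert evaluate_expression(parse_expression(text), ctx) == expected

    def test_month_shift_clamps_day_of_month(self, bp_indicator,
                                             empty_repo):
        ctx = _ctx(bp_indicator, empty_repo)
        expr = parse_expression("@2016-08-31T00:00:00 + 6 months")
        assert evaluate_expression(expr, ctx) == datetime(2017, 2, 28)

    def test_null_where_condition_drops_row(self, bp_indicator, bp_schema):
        repo = Repository(bp_schema)
        _add(repo, BP, None, "P1", datetime(2016, 5, 1),
             {SYS_PATH: Quantity(130, "mmHg"), DIA_PATH: None})
        ctx = _ctx(bp_indicator, repo)
        expr = parse_expression("Count([BP] where E0502 < 90)")
        assert evaluate_expression(expr, ctx) == 0

    def test_last_by_time_breaks_ties_by_load_order(self, bp_indicator,
                                                    bp_schema):
        repo = Repository(bp_schema)
        t = datetime(2016, 5, 1)
        for sys in (150, 120):
            _add(repo, BP, None, "P1", t,
                 {SYS_PATH: Quantity(sys, "mmHg"),
                  DIA_PATH: Quantity(80, "mmHg")})
        ctx = _ctx(bp_indicator, repo)
        expr = parse_expression(
            "Last([BP] sort by entry_time).E0501")
        assert evaluate_expression(expr, ctx) == Quantity(120, "mmHg")

    def test_during_on_non_temporal_operand_raises(self, bp_indicator,
                                                   empty_repo):
        ctx = _ctx(bp_indicator, empty_repo)
        with pytest.raises(EvalTypeError):
            evaluate_expression(
                parse_expression("3 during MeasurementPeriod"), ctx)

    def test_binding_predicates_filter_retrieves(self, bp_indicator,
                                                 bp_schema):
        # the BP binding requires positive systolic and diastolic values
        repo = Repository(bp_schema)
        _add(repo, BP, None, "P1", datetime(2016, 5, 1),
             {SYS_PATH: Quantity(0, "mmHg"), DIA_PATH: Quantity(0, "mmHg")})
        ctx = _ctx(bp_indicator, repo)
        assert evaluate_expression(parse_expression("Count([BP])"), ctx) == 0


class TestEvaluatePopulation:
    def test_empty_repository_all_sets_empty_score_undefined(
            self, bp_indicator, empty_repo):
        result = evaluate_population(bp_indicator, empty_repo)
        assert result.initial_population == set()
        assert result.numerator == set()
        assert result.score is None

    def test_single_controlled_patient_scores_one(self, bp_indicator,
                                                  single_patient_repo):
        result = evaluate_population(bp_indicator, single_patient_repo)
        assert result.initial_population == {"P1"}
        assert result.denominator == {"P1"}
        assert result.numerator == {"P1"}
        assert result.score == Fraction(1, 1)

    def test_generated_cohort_matches_ledger_exactly(self, bp_indicator,
                                                     make_cohort):
        _, repo, ledger = make_cohort(n=200, seed=7)
        result = evaluate_population(bp_indicator, repo)
        expected = ledger.population_sets()
        for pop in ("initial_population", "denominator",
                    "denominator_exclusions", "numerator"):
            assert getattr(result, pop) == expected[pop], pop

    def test_missing_parameter_raises(self, bp_indicator,
                                      single_patient_repo):
        ind = copy.deepcopy(bp_indicator)
        ind.parameters[0].default_value = None
        with pytest.raises(MissingParameterError):
            evaluate_population(ind, single_patient_repo)

    def test_parameter_override_shifts_the_period(self, bp_indicator,
                                                  single_patient_repo):
        result = evaluate_population(
            bp_indicator, single_patient_repo,
            {"MeasurementPeriod":
             "2014-01-01T00:00:00..2015-01-01T00:00:00"})
        # diagnosis and blood pressure fall outside the earlier period
        assert result.initial_population == set()

    def test_determinism_and_patient_order_invariance(self, bp_indicator,
                                                      make_cohort,
                                                      tmp_path):
        import pandas as pd
        d, repo, _ = make_cohort(n=80, seed=13)
        first = evaluate_population(bp_indicator, repo)
        again = evaluate_population(
            bp_indicator, load_fixture(d, repo.schema))
        assert first.counts() == again.counts()
        assert first.numerator == again.numerator
        # permute row order in every table
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        import os
        for name in os.listdir(d):
            if name.endswith(".csv"):
                df = pd.read_csv(os.path.join(d, name), dtype=str,
                                 keep_default_na=False)
                df = df.sample(frac=1, random_state=99)
                df.to_csv(shuffled / name, index=False)
            else:
                (shuffled / name).write_text(
                    open(os.path.join(d, name)).read())
        permuted = evaluate_population(
            bp_indicator, load_fixture(str(shuffled), repo.schema))
        assert permuted.counts() == first.counts()

    def test_score_monotonicity_under_patient_addition(self, bp_indicator,
                                                       make_cohort):
        _, repo, _ = make_cohort(n=60, seed=21)
        base = evaluate_population(bp_indicator, repo)
        assert base.score is not None and base.score < 1

        def add_patient(pid, controlled):
            _add(repo, PAT, None, pid, datetime(2010, 1, 1),
                 {PAT_ID: pid})
            _add(repo, BIRTH, TPL, pid, datetime(2010, 1, 1),
                 {BIRTH_DATE: datetime(1970, 6, 15)})
            _add(repo, DIAG, None, pid, datetime(2014, 1, 1),
                 {DIAG_CODE: Coded("ICD-10", "I10"),
                  DIAG_DATE: datetime(2014, 1, 1)})
            sys = 118 if controlled else 162
            _add(repo, BP, None, pid, datetime(2016, 9, 9),
                 {SYS_PATH: Quantity(sys, "mmHg"),
                  DIA_PATH: Quantity(74, "mmHg")})

        add_patient("PX_NUM", controlled=True)
        with_num = evaluate_population(bp_indicator, repo)
        assert with_num.score >= base.score

        add_patient("PX_DEN", controlled=False)
        with_den = evaluate_population(bp_indicator, repo)
        assert with_den.score <= with_num.score


class TestEvaluateForPatient:
    def test_esrd_before_period_sets_exclusion_flag(self, bp_indicator,
                                                    make_cohort):
        _, repo, _ = make_cohort(n=20, seed=7)
        # P00009 is the planted renal-exclusion boundary patient
        ev = evaluate_for_patient(bp_indicator, repo, "P00009")
        assert ev.flags["denominator"] is True
        assert ev.flags["denominatorexclusions"] is True

    def test_age_86_fails_initial_population(self, bp_indicator,
                                             make_cohort):
        _, repo, _ = make_cohort(n=20, seed=7)
        ev = evaluate_for_patient(bp_indicator, repo, "P00004")
        assert ev.flags["initialpopulation"] is False

    def test_late_diagnosis_fails_initial_population(self, bp_indicator,
                                                     make_cohort):
        _, repo, _ = make_cohort(n=20, seed=7)
        assert evaluate_for_patient(bp_indicator, repo, "P00006").flags[
            "initialpopulation"] is False
        assert evaluate_for_patient(bp_indicator, repo, "P00005").flags[
            "initialpopulation"] is True

    def test_intermediate_define_values_are_exposed(self, bp_indicator,
                                                    make_cohort):
        _, repo, _ = make_cohort(n=20, seed=7)
        ev = evaluate_for_patient(bp_indicator, repo, "P00002")
        assert "MostRecentBP" in ev.defines
        assert "HypertensionOnset" in ev.defines

    def test_unknown_patient_raises(self, bp_indicator, make_cohort):
        _, repo, _ = make_cohort(n=10, seed=7)
        with pytest.raises(UnknownPatientError):
            evaluate_for_patient(bp_indicator, repo, "NOBODY")

    def test_agrees_with_population_evaluation(self, bp_indicator,
                                               make_cohort):
        _, repo, ledger = make_cohort(n=60, seed=9)
        result = evaluate_population(bp_indicator, repo)
        for pid in list(ledger.patients)[:25]:
            ev = evaluate_for_patient(bp_indicator, repo, pid)
            assert ev.flags["initialpopulation"] == (
                pid in result.initial_population)


class TestCountMeasure:
    def test_icu_count_equals_brute_force(self, apache_indicator,
                                          make_icu_cohort):
        import _oracles
        d, repo, ledger = make_icu_cohort(n=100, seed=3)
        result = evaluate_population(apache_indicator, repo)
        assert result.measure_type == "count"
        assert int(result.observation_total) == _oracles.apache_count(d)
        assert int(result.observation_total) == ledger.expected_count

    def test_score_at_exactly_24h_is_counted(self, apache_indicator,
                                             make_icu_cohort):
        # patient ICU00001 carries score 15 at exactly admission + 24 h
        _, repo, _ = make_icu_cohort(n=3, seed=1)
        result = evaluate_population(apache_indicator, repo)
        assert "ICU00001" in result.observations
        assert "ICU00002" not in result.observations  # 1 s past the window
        assert "ICU00003" not in result.observations  # score below 15


class TestParamParsing:
    def test_interval_datetime_and_code_forms(self):
        decl = ParameterDecl("MP", "Interval<DateTime>")
        iv = parse_param_value(decl,
                               "2016-01-01T00:00:00..2017-01-01T00:00:00")
        assert iv.low == datetime(2016, 1, 1) and not iv.high_closed
        assert parse_param_value(ParameterDecl("D", "DateTime"),
                                 "2016-05-01T10:30:00") == \
            datetime(2016, 5, 1, 10, 30)
        assert parse_param_value(ParameterDecl("N", "Integer"), "15") == 15
        assert parse_param_value(ParameterDecl("C", "Code"),
                                 "ICD-10|I10") == Coded("ICD-10", "I10")
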