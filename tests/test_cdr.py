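"""Repository schema derivation, typed loading and retrieval."""

from datetime import datetime
from random import Random

import pytest

from cqi.cdr import (CdrTypeError, Coded, EntryRecord, Quantity, Repository,
                     SchemaMismatchError, TimeInterval, UnknownTableError,
                     format_cell, load_fixture, parse_cell,
                     schema_from_indicator, table_filename, write_fixture)
from cqi.model import TermBinding, TermRef
from cqi.terminology import default_registry, resolve_binding

BP_ARCHETYPE = "openEHR-EHR-OBSERVATION.blood_pressure.v1"
SYS_PATH = "/data[at0001]/events[at0006]/data[at0003]/items[at0004]/value"
DIA_PATH = "/data[at0001]/events[at0006]/data[at0003]/items[at0005]/value"


class TestSchemaFromIndicator:
    def test_bp_table_has_systolic_and_diastolic_columns(self, bp_schema):
        table = bp_schema.require(BP_ARCHETYPE, None)
        assert SYS_PATH in table.paths and DIA_PATH in table.paths

    def test_one_table_per_archetype_template_pair(self, bp_schema):
        keys = set(bp_schema.tables)
        assert (BP_ARCHETYPE, None) in keys
        assert ("openEHR-DEMOGRAPHIC-CLUSTER.person_birth_data_iso.v1",
                "patient_demographics.t.v1") in keys

    def test_two_aliases_same_archetype_share_one_table(self, bp_indicator):
        import copy
        from cqi.model import (ArchetypeBinding, DefineStatement,
                               ElementBinding, Retrieve)
        ind = copy.deepcopy(bp_indicator)
        ind.archetype_bindings.append(ArchetypeBinding(
            alias="BP2", archetype_id=BP_ARCHETYPE,
            elements=[ElementBinding("E0901", "/protocol/extra/value")]))
        ind.defines.append(DefineStatement("ExtraBP",
                                           Retrieve(alias="BP2")))
        schema = schema_from_indicator(ind)
        table = schema.require(BP_ARCHETYPE, None)
        assert "/protocol/extra/value" in table.paths
        assert SYS_PATH in table.paths


class TestCellTyping:
    @pytest.mark.parametrize("text, value", [
        ("ICD-10|I10", Coded("ICD-10", "I10")),
        ("138|mmHg", Quantity(138.0, "mmHg")),
        ("2016-05-01T10:30:00", datetime(2016, 5, 1, 10, 30)),
        ("85", 85),
        ("3.5", 3.5),
        ("true", True),
        ("free text", "free text"),
        ("", None),
    ])
    def test_lexical_shape_decides_type(self, text, value):
        assert parse_cell(text) == value

    @pytest.mark.parametrize("value", [
        Coded("ICD-10", "N18.6"), Quantity(139.0, "mmHg"),
        Quantity(120.25, "mmHg"), datetime(2016, 12, 31, 23, 59, 59),
        17, -3.25, True, "note",
    ])
    def test_format_parse_round_trip_is_exact(self, value):
        assert parse_cell(format_cell(value)) == value


class TestLoadFixture:
    def test_empty_cohort_loads_and_is_evaluable(self, tmp_path, bp_schema,
                                                 bp_indicator):
        from cqi.engine import evaluate_population
        write_fixture(str(tmp_path), bp_schema, {})
        repo = load_fixture(str(tmp_path), bp_schema)
        assert repo.patients() == []
        result = evaluate_population(bp_indicator, repo)
        assert result.score is None

    def test_row_counts_match_generator(self, make_cohort):
        d, repo, _ = make_cohort(n=50, seed=11)
        from cqi.syndata import CohortSpec, generate_cohort
        import tempfile
        with tempfile.TemporaryDirectory() as d2:
            counts, _ = generate_cohort(CohortSpec(n_patients=50, seed=11),
                                        d2)
        assert repo.row_counts() == counts

    def test_missing_column_is_schema_mismatch(self, tmp_path, bp_schema):
        import pandas as pd
        fname = tmp_path / table_filename(BP_ARCHETYPE, None)
        pd.DataFrame({"patient_id": ["P1"],
                      "entry_time": ["2016-01-01T00:00:00"],
                      DIA_PATH: ["80|mmHg"]}).to_csv(fname, index=False)
        with pytest.raises(SchemaMismatchError, match="at0004"):
            load_fixture(str(tmp_path), bp_schema)

    def test_mixed_column_types_report_row_number(self, tmp_path, bp_schema):
        import pandas as pd
        fname = tmp_path / table_filename(BP_ARCHETYPE, None)
        pd.DataFrame({
            "patient_id": ["P1", "P1"],
            "entry_time": ["2016-01-01T00:00:00", "2016-02-01T00:00:00"],
            SYS_PATH: ["120|mmHg", "oops"],
            DIA_PATH: ["80|mmHg", "70|mmHg"],
        }).to_csv(fname, index=False)
        with pytest.raises(CdrTypeError, match="row 3"):
            load_fixture(str(tmp_path), bp_schema)

    def test_load_retrieve_round_trip_is_bit_exact(self, make_cohort):
        d, repo, _ = make_cohort(n=40, seed=2)
        rows = repo.retrieve(BP_ARCHETYPE)
        reloaded = load_fixture(d, repo.schema).retrieve(BP_ARCHETYPE)
        assert [(r.patient_id, r.entry_time, r.values) for r in rows] == \
               [(r.patient_id, r.entry_time, r.values) for r in reloaded]


class TestRetrieve:
    @pytest.fixture()
    def repo(self, make_cohort):
        return make_cohort(n=120, seed=5)[1]

    @pytest.fixture()
    def htn_vs(self):
        return resolve_binding(
            TermBinding("HTN", refs=[TermRef("ICD-10", "I10")]),
            default_registry())

    DIAG = "openEHR-EHR-EVALUATION.problem_diagnosis.v1"
    DIAG_CODE = "/data[at0001]/items[at0002]/value"

    def test_unknown_archetype_raises(self, repo):
        with pytest.raises(UnknownTableError):
            repo.retrieve("openEHR-EHR-OBSERVATION.nonexistent.v9")

    def test_half_open_window_excludes_upper_bound(self, bp_schema):
        repo = Repository(bp_schema)
        for i, t in enumerate([datetime(2016, 6, 1),
                               datetime(2017, 1, 1)]):
            repo.add(BP_ARCHETYPE, None, EntryRecord(
                patient_id="P1", archetype_id=BP_ARCHETYPE, entry_time=t,
                values={SYS_PATH: Quantity(120, "mmHg"),
                        DIA_PATH: Quantity(80, "mmHg")}))
        window = TimeInterval(datetime(2016, 1, 1), datetime(2017, 1, 1))
        got = repo.retrieve(BP_ARCHETYPE, time_window=window)
        assert [r.entry_time for r in got] == [datetime(2016, 6, 1)]

    def test_filters_are_anti_monotone(self, repo, htn_vs):
        full = repo.retrieve(self.DIAG)
        coded = repo.retrieve(self.DIAG,
                              term_filter=(self.DIAG_CODE, htn_vs))
        windowed = repo.retrieve(
            self.DIAG, term_filter=(self.DIAG_CODE, htn_vs),
            time_window=TimeInterval(datetime(2015, 1, 1),
                                     datetime(2016, 1, 1)))
        ids = lambda rows: {r.uid for r in rows}
        assert ids(windowed) <= ids(coded) <= ids(full)

    def test_matches_brute_force_scan_on_random_filters(self, repo, htn_vs):
        """Randomized filter combinations against a direct row scan."""
        rng = Random(0)
        reg = default_registry()
        all_rows = repo.retrieve(self.DIAG)
        for _ in range(25):
            term = (self.DIAG_CODE, htn_vs) if rng.random() < 0.5 else None
            window = None
            if rng.random() < 0.7:
                lo = datetime(2010 + rng.randint(0, 6), 1, 1)
                window = TimeInterval(lo, lo.replace(
                    year=lo.year + rng.randint(1, 3)))
            pid = None
            if rng.random() < 0.4 and repo.patients():
                pid = rng.choice(repo.patients())
            got = repo.retrieve(self.DIAG, term_filter=term,
                                time_window=window, patient_id=pid)
            expected = []
            for r in all_rows:
                if pid is not None and r.patient_id != pid:
                    continue
                if term is not None:
                    v = r.values.get(self.DIAG_CODE)
                    if not (isinstance(v, Coded)
                            and (v.system, v.code) in htn_vs):
                        continue
                if window is not None and not (
                        window.low <= r.entry_time < window.high):
                    continue
                expected.append(r)
            key = lambda r: (r.patient_id, r.entry_time, r.uid[1])
            assert [key(r) for r in got] == sorted(key(r) for r in expected)
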