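import pytest

import cqi
from cqi.cdr import load_fixture, schema_from_indicator
from cqi.syndata import CohortSpec, generate_cohort, generate_icu_cohort


@pytest.fixture(scope="session")
def bp_indicator():
    return cqi.load_fixture_indicator(cqi.BP_FIXTURE)


@pytest.fixture(scope="session")
def apache_indicator():
    return cqi.load_fixture_indicator(cqi.APACHE_FIXTURE)


@pytest.fixture(scope="session")
def bp_schema(bp_indicator):
    return schema_from_indicator(bp_indicator)


@pytest.fixture()
def make_cohort(tmp_path, bp_schema):
    """Generate a BP cohort in a temp dir; returns (dir, repo, ledger)."""

    def _make(n=200, seed=7, **overrides):
        d = tmp_path / f"cohort_{seed}_{n}"
        d.mkdir(exist_ok=True)
        _, ledger = generate_cohort(
            CohortSpec(n_patients=n, seed=seed, **overrides), str(d))
        repo = load_fixture(str(d), bp_schema)
        return str(d), repo, ledger

    return _make


@pytest.fixture()
def make_icu_cohort(tmp_path, apache_indicator):
    schema = schema_from_indicator(apache_indicator)

    def _make(n=100, seed=3, **kw):
        d = tmp_path / f"icu_{seed}_{n}"
        d.mkdir(exist_ok=True)
        _, ledger = generate_icu_cohort(n, seed, out_dir=str(d), **kw)
        repo = load_fixture(str(d), schema)
        return str(d), repo, ledger

    return _make
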