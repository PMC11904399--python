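import pytest

import ffqkit as fk
from ffqkit.derivation import DerivationEngine


@pytest.fixture(scope="session")
def schema():
    return fk.pregnancy_schema()


@pytest.fixture(scope="session")
def portions():
    return fk.packaged_portion_table()


@pytest.fixture(scope="session")
def composition(portions):
    return fk.synthetic_composition(portions)


@pytest.fixture(scope="session")
def engine(portions, composition, schema):
    return DerivationEngine(portions, composition, schema=schema)


@pytest.fixture
def make_response():
    """Factory for schema-valid responses with everything missing except
    the given answers."""

    def _make(answers=None, pid="P000001"):
        return fk.FfqResponse(participant_id=pid, answers=dict(answers or {}))

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant default cohort shared across tests."""
    return fk.generate_cohort(fk.CohortConfig(n=300), seed=20260928)
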