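import pytest

from degradesign import data, reference
from degradesign.tables_io import doe_to_design


@pytest.fixture(scope="session")
def effects_records():
    return data.load_opfr_effects()


@pytest.fixture(scope="session")
def effects_frame():
    return data.load_opfr_effects_frame()


@pytest.fixture(scope="session")
def doe_runs():
    return data.load_taguchi_runs()


@pytest.fixture(scope="session")
def doe_design(doe_runs):
    design, responses = doe_to_design(doe_runs, reference.EXTERNAL_FACTORS)
    return design, responses
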