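import pytest

from tsunevac import ModelParameters, load_kochi_table


@pytest.fixture(scope="session")
def kochi_rows():
    return load_kochi_table()


@pytest.fixture(scope="session")
def kochi_by_id(kochi_rows):
    return {r.recipient_id: r for r in kochi_rows}


@pytest.fixture(scope="session")
def base_params():
    return ModelParameters()
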