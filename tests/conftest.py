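import pytest

from dementia_cea import evaluate, load_parameters


@pytest.fixture(scope="session")
def primary_params():
    return load_parameters(setting="primary_care")


@pytest.fixture(scope="session")
def memory_params():
    return load_parameters(setting="memory_clinic")


@pytest.fixture(scope="session")
def primary_result(primary_params):
    return evaluate(primary_params)


@pytest.fixture(scope="session")
def memory_result(memory_params):
    return evaluate(memory_params)
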