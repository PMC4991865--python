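import pytest

from remiseta import decompose_matrix, load_fixture


@pytest.fixture(scope="session")
def matrix_a():
    return load_fixture("A")


@pytest.fixture(scope="session")
def matrix_f():
    return load_fixture("F")


@pytest.fixture(scope="session")
def model_a(matrix_a):
    return decompose_matrix(matrix_a)


@pytest.fixture(scope="session")
def model_f(matrix_f):
    return decompose_matrix(matrix_f)
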