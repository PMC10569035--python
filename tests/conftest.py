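import pytest

from tpcurate import fixtures as fx


@pytest.fixture(scope="session")
def catalog():
    return fx.catalog()


@pytest.fixture(scope="session")
def annotation_fixture():
    """Annotation fixture at the reference conditions: 50 compounds,
    3 excerpts each, 400 spans, 20% true."""
    return fx.gen_annotation_fixture(seed=1)


@pytest.fixture(scope="session")
def library_fixture():
    return fx.gen_library_fixture(seed=11)


@pytest.fixture(scope="session")
def screening_fixture():
    return fx.gen_screening_fixture(seed=5)
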