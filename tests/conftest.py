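import warnings

import pytest

from contextgem import fixtures as fx


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Silence advisory warnings (partial media, dropped core members) in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def chain():
    return fx.make_toy_model("chain")


@pytest.fixture
def diamond():
    return fx.make_toy_model("diamond")


@pytest.fixture
def dead_end():
    return fx.make_toy_model("dead_end")


@pytest.fixture
def isozyme():
    return fx.make_toy_model("isozyme")


@pytest.fixture
def parallel_paths():
    return fx.make_toy_model("parallel_paths")


@pytest.fixture
def minimal_medium():
    return fx.make_toy_model("minimal_medium")
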