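import pytest
from hypothesis import settings

from ilfkit import TruthTable, builtin_function, default_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ideal_library():
    return default_library("ideal_step")


@pytest.fixture(scope="session")
def graded_library():
    return default_library("graded")


@pytest.fixture(scope="session")
def majority():
    return builtin_function("majority3")


@pytest.fixture(scope="session")
def comparator():
    return builtin_function("comparator2bit")


@pytest.fixture(scope="session")
def mux():
    return builtin_function("mux4to1")


def table_from_bits(bits: int, n: int, names=None) -> TruthTable:
    """Single-output table whose on-set is encoded in the integer ``bits``."""
    names = names or tuple(f"x{k}" for k in range(n))
    on = frozenset(m for m in range(1 << n) if bits >> m & 1)
    return TruthTable(names, ("f",), {"f": on})
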