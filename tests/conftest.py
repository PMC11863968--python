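import pytest

from guidex import build_index, load_cfd_table, random_genome


@pytest.fixture(scope="session")
def cfd_table():
    return load_cfd_table()


@pytest.fixture(scope="session")
def small_genome():
    """10 kb deterministic random genome shared by read-only tests."""
    return random_genome(10_000, gc=0.5, seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome)
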