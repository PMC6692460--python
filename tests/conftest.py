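import pytest

from kininmine import CleavageRuleSet, load_tick_kinins


@pytest.fixture(scope="session")
def tick_kinins():
    """The bundled published kinin table (both species)."""
    return load_tick_kinins()


@pytest.fixture(scope="session")
def rm_kinins(tick_kinins):
    return tick_kinins[tick_kinins.species == "Rhipicephalus microplus"].reset_index(drop=True)


@pytest.fixture(scope="session")
def ix_kinins(tick_kinins):
    return tick_kinins[tick_kinins.species == "Ixodes scapularis"].reset_index(drop=True)


@pytest.fixture(scope="session")
def default_rules():
    return CleavageRuleSet()
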