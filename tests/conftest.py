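import pytest

from oglycosim import GolgiLayout, build_network, load_ruleset

CHO_WT_RULES = ["C1GALT1", "ST3GAL_a", "ST6GALNAC_a", "ST6GALNAC_b", "ST6GALNAC_c"]


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset()


@pytest.fixture(scope="session")
def layout():
    return GolgiLayout.default()


@pytest.fixture(scope="session")
def cho_wt_network(ruleset):
    return build_network(ruleset, CHO_WT_RULES)
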