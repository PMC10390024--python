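"""Shared fixtures: generated reaction sets and oracle backends."""

import pytest

import retrotag as rt

ESTERIFICATION = (
    "[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][CH2:6][OH:7]"
    ">>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5]"
)
DIELS_ALDER = (
    "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
    ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1"
)


@pytest.fixture(scope="session")
def esterification():
    return rt.parse_reaction_line(ESTERIFICATION)


@pytest.fixture(scope="session")
def fixture_set():
    """200 clean single-site reactions across all five templates."""
    return rt.generate_dataset(200, seed=42)


@pytest.fixture(scope="session")
def spectator_set():
    """Reactions guaranteed to carry unmapped spectator species."""
    fx = rt.generate_dataset(120, seed=11, spectator_prob=0.6)
    return [f for f in fx if f.spectators]


@pytest.fixture(scope="session")
def enzymatic_set():
    return rt.generate_dataset(60, seed=5, ec_mode=True)


@pytest.fixture(scope="session")
def multi_site_set():
    return rt.multi_site_products(30, seed=3)


@pytest.fixture(scope="session")
def oracle():
    return rt.TemplateOracleTranslator()


@pytest.fixture(scope="session")
def naive():
    return rt.NaiveTranslator()


@pytest.fixture(scope="session")
def forward():
    return rt.TemplateForwardModel()


@pytest.fixture(scope="session")
def mapper():
    return rt.OracleAtomMapper()


@pytest.fixture(scope="session")
def classifier():
    return rt.TemplateClassifier()
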