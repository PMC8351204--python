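import pytest

from readacross import Compound, generate_fixture_library


@pytest.fixture(scope="session")
def paraben_bundle():
    return generate_fixture_library("parabens")


@pytest.fixture(scope="session")
def hair_dye_bundle():
    return generate_fixture_library("hair_dyes")


@pytest.fixture()
def propyl_paraben():
    return Compound.from_smiles("CMS-2411", "CCCOC(=O)c1ccc(O)cc1", "Propyl paraben", "94-13-3")


@pytest.fixture()
def benzene():
    return Compound.from_smiles("benzene", "c1ccccc1")
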