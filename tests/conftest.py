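import pytest
from rdkit import RDLogger

from drugspace import GeneratorSpec, fixture_molecules, generate_library
from drugspace.pipeline import profile_records

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def fixtures():
    return fixture_molecules()


@pytest.fixture(scope="session")
def library_records():
    """A mid-sized synthetic library shared across test modules."""
    return generate_library(GeneratorSpec(n=120, seed=3))


@pytest.fixture(scope="session")
def library_profile(library_records):
    return profile_records(library_records)
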