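import pytest

from tertkit import load_builtin_matrix
from tertkit.platypus_model import build_platypus_fixture
from tertkit.simulate import FamilyProfile, simulate_tert_family


@pytest.fixture(scope="session")
def blosum62():
    return load_builtin_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def platypus():
    """The packaged 16-exon worked-example gene model and its 7 events."""
    model, events = build_platypus_fixture()
    return model, events


@pytest.fixture(scope="session")
def planted_family():
    """Four-species family with planted linker lengths spanning all classes."""
    profile = FamilyProfile(
        n_species=4,
        linker_lengths=[(150, 100, 50), (120, 90, 90), (90, 60, 30), (30, 20, 10)],
        species_ids=["ref", "longy", "mediumy", "shorty"],
        seed=11,
    )
    return simulate_tert_family(profile)
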