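import pytest

from muroseek import reference
from muroseek.database import CrosslinkRules, build_database


@pytest.fixture(scope="session")
def composition_table():
    """The bundled G. oxydans B58 composition reference."""
    return reference.load_composition()


@pytest.fixture(scope="session")
def db0(composition_table):
    """Curated monomer names (DB0) for G. oxydans B58."""
    return reference.db0_monomers(composition_table)


@pytest.fixture(scope="session")
def full_db(db0):
    """Generated theoretical database with all cross-link rules enabled."""
    return build_database(db0, CrosslinkRules())


@pytest.fixture(scope="session")
def db_names(full_db):
    names = set()
    for e in full_db:
        names.update(e.names)
    return names
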