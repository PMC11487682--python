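import pytest

import vhhkit as vk
from vhhkit.simulate import RepertoireConfig, generate_repertoire


@pytest.fixture(scope="session")
def db():
    return vk.default_germline_db()


@pytest.fixture(scope="session")
def ferg(db):
    """Camelid FERG germline (carries the germline Cys55)."""
    return db.by_name("syncam-VHH-FERG*01").numbered


@pytest.fixture(scope="session")
def human(db):
    return db.by_name("synhum-VH3-VGLW*01").numbered


@pytest.fixture(scope="session")
def repertoire():
    """Coupled synthetic repertoire shared by the slower statistics tests."""
    cfg = RepertoireConfig(n_sequences=2000, seed=11)
    return generate_repertoire(cfg)
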