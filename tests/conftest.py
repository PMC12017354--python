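import logging

import pytest

from narrafnirs.datatypes import CohortSpec, SessionLayout
from narrafnirs.lexicon import build_default_lexicon

logging.getLogger("narrafnirs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_session():
    """Short session layout that keeps unit tests fast but valid."""
    return SessionLayout(rest_s=60.0, digits1_s=15.0, narration_s=60.0,
                         digits2_s=15.0)


@pytest.fixture(scope="session")
def tiny_spec(tiny_session):
    return CohortSpec(n_ptsd=4, n_tec=4, seed=7, session=tiny_session)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=42)


@pytest.fixture(scope="session")
def lexicon():
    return build_default_lexicon()
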