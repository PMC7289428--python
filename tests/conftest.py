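import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from beehex import (  # noqa: E402
    CommunitySpec,
    hymenopteran_receptors,
    make_community,
    make_illuminant,
    make_leaf_background,
)


@pytest.fixture(scope="session")
def background():
    return make_leaf_background()


@pytest.fixture(scope="session")
def illuminant():
    return make_illuminant()


@pytest.fixture(scope="session")
def receptors():
    return hymenopteran_receptors()


@pytest.fixture(scope="session")
def community():
    """A default synthetic community with the study's subset structure."""
    frame, spectra = make_community(CommunitySpec(seed=42))
    return frame, spectra
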