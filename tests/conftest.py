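from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import ircmech as m

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def wiberg_text() -> str:
    return (DATA / "wiberg_block.txt").read_text()


@pytest.fixture(scope="session")
def base_bundle():
    """base_assisted_like preset bundle (stepwise, dissociative)."""
    return m.generate_path(m.preset("base_assisted_like"))


@pytest.fixture(scope="session")
def substrate_bundle():
    """substrate_assisted_like preset bundle (concerted, dissociative)."""
    return m.generate_path(m.preset("substrate_assisted_like"))


@pytest.fixture()
def triangle_frame() -> m.Frame:
    """Right-angle construction: O at origin, P on x, O on y."""
    return m.Frame(frame_index=0, coords=np.array([
        [0.0, 0.0, 0.0],
        [2.0, 0.0, 0.0],
        [0.0, 1.5, 0.0],
    ]))
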