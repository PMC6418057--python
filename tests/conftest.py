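"""Shared fixtures: small phantoms and blocks, generated at test time."""

import numpy as np
import pytest

from jointload.synthetic import (
    PhantomSpec,
    generate_metacarpal_phantom,
    generate_uniform_block,
)


@pytest.fixture(scope="session")
def phantom():
    """One standard straight phantom (session-cached; ~0.1 s to build)."""
    return generate_metacarpal_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def solid_phantom():
    """Phantom with zero porosity (fully solid interior)."""
    return generate_metacarpal_phantom(
        PhantomSpec(seed=0, porosity_target=0.0))


@pytest.fixture(scope="session")
def bent_phantom():
    """Long solid phantom bowed dorsally with a 40 mm surface arc."""
    return generate_metacarpal_phantom(
        PhantomSpec(shaft_length_mm=30.0, porosity_target=0.0,
                    dorsal_arc_radius_mm=40.0, seed=0))


@pytest.fixture()
def block():
    return generate_uniform_block((6, 6, 6), 0.06)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
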