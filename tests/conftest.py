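"""Shared synthetic fixtures.

Slide generation is deterministic given the spec seed, so session scope is
safe: fixtures are never mutated by tests (tests copy before writing).
"""

import numpy as np
import pytest

from pollenvision import SyntheticSlideSpec, TextureParams, generate_slide
from pollenvision import study


@pytest.fixture(scope="session")
def small_spec():
    """A cheap slide spec for unit tests (160 px, 6 grains, 1 z-plane)."""
    return SyntheticSlideSpec(
        height=160, width=160, n_grains=6, radius_range=(12, 18),
        n_z_planes=1, seed=7,
    )


@pytest.fixture(scope="session")
def small_slide(small_spec):
    return generate_slide(small_spec)


@pytest.fixture(scope="session")
def reference_slides():
    """The 12-slide pure reference design at desk scale."""
    return study.make_reference_slides(seed=42)


@pytest.fixture(scope="session")
def ratio_slides():
    """The 22-slide mixed-ratio series at desk scale."""
    return study.make_ratio_slides(seed=99)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
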