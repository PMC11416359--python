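"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pytest

from sonomargin import phantom

# the degenerate-TT warning is expected on thin tumor tips
warnings.filterwarnings(
    "ignore", message="tumor spans a single pixel row"
)


@lru_cache(maxsize=16)
def _phantom_cached(seed: int, items: tuple) -> phantom.PhantomSpecimen:
    config = phantom.sample_config(seed, **dict(items))
    return phantom.generate_phantom(config, specimen=f"S{seed}")


def make_phantom(seed: int, **overrides) -> phantom.PhantomSpecimen:
    return _phantom_cached(seed, tuple(sorted(overrides.items())))


@pytest.fixture(scope="session")
def default_phantom() -> phantom.PhantomSpecimen:
    """One deterministic identity-transform phantom (defaults, seed 0)."""
    return phantom.generate_phantom(phantom.PhantomConfig(seed=0), specimen="P1")


@pytest.fixture(scope="session")
def random_phantom() -> phantom.PhantomSpecimen:
    """One randomized identity-transform phantom."""
    return phantom.generate_phantom(phantom.sample_config(5), specimen="P1")


@pytest.fixture(scope="session")
def shrunk_phantom() -> phantom.PhantomSpecimen:
    """One randomized phantom with 20% uniform shrinkage."""
    return phantom.generate_phantom(
        phantom.sample_config(5, shrinkage=0.2), specimen="P1"
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
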