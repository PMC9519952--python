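"""Shared fixtures: small seeded phantoms reused across test modules."""

import numpy as np
import pytest

from tissueqc import bmode, synthetic as syn


@pytest.fixture(scope="session")
def void_phantom():
    """One RF phantom with a 10% centered void, reconstructed to B-mode."""
    spec = syn.RfPhantomSpec(seed=42).with_centered_void(10.0)
    vol, truth = syn.gen_rf_phantom(spec)
    bm = bmode.reconstruct_volume(vol)
    return spec, bm, truth


@pytest.fixture(scope="session")
def voidfree_phantom():
    """Void-free RF phantom, reconstructed to B-mode."""
    spec = syn.RfPhantomSpec(seed=42)
    vol, truth = syn.gen_rf_phantom(spec)
    bm = bmode.reconstruct_volume(vol)
    return spec, bm, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
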