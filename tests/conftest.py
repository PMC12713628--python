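"""Shared fixtures.

The expensive artifacts — the synthetic training family, the trained
AptaVAE, the SELEX simulation, and the trained pool VAEs — are built once
per session and shared across integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dlselex.aptaclux import CluxConfig, train_aptaclux
from dlselex.aptavae import ModelConfig, train_aptavae
from dlselex.synthesim import (
    SyntheticFamilySpec,
    SyntheticSelexSpec,
    gen_pairs,
    simulate_selex,
)

SESSION_SEED = 11


@pytest.fixture(scope="session")
def family():
    """The synthetic training family at study-condition defaults."""
    return gen_pairs(SyntheticFamilySpec(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def trained_aptavae(family):
    """AptaVAE trained at full scale (195 pairs, 8 classes, 256-d latent)."""
    return train_aptavae(family.pairs, ModelConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def selex_sim():
    """Simulated SELEX rounds 3/5/7 with a planted binder."""
    return simulate_selex(SyntheticSelexSpec(seed=7))


@pytest.fixture(scope="session")
def trained_clux_r3(selex_sim):
    return train_aptaclux(selex_sim.pools[3], CluxConfig(seed=7))


@pytest.fixture(scope="session")
def trained_clux_r5(selex_sim):
    return train_aptaclux(selex_sim.pools[5], CluxConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
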