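"""Shared fixtures: small synthetic sessions, generated once per test run."""

import numpy as np
import pytest

from corticostate import spectroscopy, synthetic_data as sd


@pytest.fixture(scope="session")
def optics():
    return spectroscopy.OpticalModel()


@pytest.fixture(scope="session")
def small_config():
    """Compact still session (no locomotion) for spectroscopy/preprocessing."""
    return sd.SimConfig(duration_s=120, image_shape=(20, 18),
                        n_parcels_per_hemisphere=4, bout_rate_per_min=0.0, seed=3)


@pytest.fixture(scope="session")
def small_session(small_config, optics):
    return sd.simulate_session(small_config, optics)


@pytest.fixture(scope="session")
def active_config():
    """10-minute session with locomotion bouts, 8 parcels/hemisphere."""
    return sd.SimConfig(duration_s=600, image_shape=(24, 24),
                        n_parcels_per_hemisphere=8, seed=7)


@pytest.fixture(scope="session")
def active_session(active_config, optics):
    return sd.simulate_session(active_config, optics)


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: results don't depend on test order
    return np.random.default_rng(0)
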