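"""Shared fixtures: a small, fast synthetic-well configuration.

The small fixture scales the default well down (384² field, ~7,000 μm²
cores, 50 halo cells) so image-pipeline tests run in seconds; tests that
probe the calibrated full-scale defaults build their own wells.
"""

import numpy as np
import pytest
from hypothesis import settings

from spheroquant.synthdata import DistanceSpec, SynthParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    return SynthParams(
        image_shape=(384, 384),
        core_area_mean=12000.0,
        core_area_sd=500.0,
        n_halo_cells=50,
        n_chains=14,
        migration_distances=DistanceSpec("gamma", (2.0, 30.0)),
        dead_fraction=0.3,
        n_slices=5,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
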