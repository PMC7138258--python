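"""Shared fixtures.

Expensive Monte Carlo artifacts (hardware setup on a small grid) are
module-scoped session fixtures so the suite stays within minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cepaq.context import CIConfig
from cepaq.grid import GridSpec
from cepaq.hardware import HardwareSetup
from cepaq.mclight import SourceSpec


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(dims=(32, 24, 16))


@pytest.fixture(scope="session")
def small_setup(small_grid) -> HardwareSetup:
    """Small hardware setup with modest photon budgets, shared per session."""
    return HardwareSetup(
        grid=small_grid,
        source=SourceSpec("line"),
        seed=7,
        phi_h_photons=400_000,
        bank_batch_photons=10_000,
        bank_min_target_hits=200,
        bank_max_batches=20,
        background_stats_photons=50_000,
        ci_config=CIConfig(),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
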