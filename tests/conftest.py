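"""Shared fixtures: small simulated acquisitions reused across test modules.

All scenarios are desk-scale (32-64 px, minutes-long) versions of the
40-minute protocol; the 1:1:2 normoxia/hypoxia/normoxia split is preserved
so epoch-dependent logic is exercised end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

from hypoxmap import ScenarioConfig, demultiplex, make_brain_mask, simulate_scenario


@pytest.fixture(scope="session")
def small_run():
    """Noise-free 32x32, 2-minute acquisition with full ground truth."""
    cfg = ScenarioConfig(image_shape=(32, 32), duration_s=120.0, noise_sd=0.0, rng_seed=11)
    stack, truth = simulate_scenario(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_channels(small_run):
    _, stack, _ = small_run
    return demultiplex(stack)


@pytest.fixture(scope="session")
def noisy_run():
    """Same scenario with default sensor noise."""
    cfg = ScenarioConfig(image_shape=(32, 32), duration_s=120.0, rng_seed=12)
    stack, truth = simulate_scenario(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def brain_mask_small(small_run):
    _, _, truth = small_run
    return make_brain_mask(truth.atlas, edge_margin_px=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
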