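"""Shared fixtures.

The desk-scale fixtures (scale 0.25: 64^3 grids, ~3,900 spokes) run the full
pipeline once per test session and are shared by the end-to-end and
acceptance tests; the small-instance fixtures (16^3 grid, 64 spokes) feed
the brute-force oracle comparisons.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from sodiumqa import acquisition as acq
from sodiumqa import recon, repeatability
from sodiumqa.config import RunConfig
from sodiumqa.phantom import PhantomConfig, VialSpec, build_phantom

warnings.filterwarnings("ignore", message="voxel size exceeds")


@pytest.fixture(scope="session")
def small_phantom():
    """Two off-center vials on a 16^3 grid (oracle-sized instance)."""
    cfg = PhantomConfig(
        grid_shape=(16, 16, 16),
        vials=[
            VialSpec("L_77", "large", 77.0, (0.05, 0.0, 0.0), 0.06, 0.15),
            VialSpec("S_154", "small", 154.0, (-0.06, 0.04, 0.02), 0.05, 0.12),
        ])
    return build_phantom(cfg)


@pytest.fixture(scope="session")
def small_params():
    # kmax matched to the 16^3 grid Nyquist: 16 samples per spoke
    return acq.AcqParams(n_spokes=64, nominal_resolution=0.384 / 16)


@pytest.fixture(scope="session")
def small_trajectory(small_params):
    return acq.build_trajectory(small_params)


@pytest.fixture(scope="session")
def small_recon_params():
    return recon.ReconParams(recon_resolution=0.384 / 16)


@pytest.fixture(scope="session")
def desk_config() -> RunConfig:
    return RunConfig(seed=1).scaled(0.25)


@pytest.fixture(scope="session")
def desk_phantom(desk_config):
    return build_phantom(desk_config.phantom)


@pytest.fixture(scope="session")
def desk_trajectory(desk_config):
    return acq.build_trajectory(desk_config.acq)


@pytest.fixture(scope="session")
def desk_noiseless(desk_phantom, desk_trajectory, desk_config):
    return acq.simulate_noiseless(desk_phantom, desk_trajectory,
                                  desk_config.acq,
                                  n_segments=desk_config.recon.n_segments)


@pytest.fixture(scope="session")
def calibrated_sigma(desk_phantom, desk_config, desk_noiseless) -> float:
    """Noise SD calibrated so the 12-average image SNR is ~79."""
    return acq.calibrate_noise_sigma(
        desk_phantom, desk_config.acq, desk_config.target_snr,
        recon_params=desk_config.recon, seed=desk_config.seed,
        noiseless=desk_noiseless)


@pytest.fixture(scope="session")
def desk_noisy_config(desk_config, calibrated_sigma) -> RunConfig:
    return dataclasses.replace(desk_config, noise_sigma=calibrated_sigma)


@pytest.fixture(scope="session")
def desk_sessions(desk_noisy_config):
    """The full 3-day x 3-scan repeatability design at SNR ~79."""
    return repeatability.run_design(desk_noisy_config)


@pytest.fixture(scope="session")
def desk_pipeline_cache(desk_noisy_config):
    cache = repeatability._PipelineCache()
    cache.prepare(desk_noisy_config)
    return cache
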