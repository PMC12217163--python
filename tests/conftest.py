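"""Shared fixtures: small simulated datasets, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lnptrace import SimulationConfig, simulate_release_experiment


SMALL = dict(n_cells=2, n_vesicles_per_cell=3, height=160, width=160,
             n_frames=40, onset_margin_s=32.0)


@pytest.fixture(scope="session")
def noiseless_release():
    """Noiseless, bleach-free field: 6 vesicles, no fast release."""
    cfg = SimulationConfig(**SMALL, read_noise_sd=0.0, photon_scaling=0.0,
                           bleach_rate_per_s=(0.0, 0.0, 0.0),
                           fast_release_fraction=0.0, hit_fraction=1.0,
                           motion_sd_px_per_frame=0.0, rng_seed=11)
    return cfg, simulate_release_experiment(cfg)


@pytest.fixture(scope="session")
def noiseless_release_step():
    """Noiseless field where every vesicle releases 50% at onset."""
    cfg = SimulationConfig(**SMALL, read_noise_sd=0.0, photon_scaling=0.0,
                           bleach_rate_per_s=(0.0, 0.0, 0.0),
                           fast_release_fraction=1.0, hit_fraction=1.0,
                           release_magnitude_fraction=0.5,
                           motion_sd_px_per_frame=0.0, rng_seed=12)
    return cfg, simulate_release_experiment(cfg)


@pytest.fixture(scope="session")
def noisy_release():
    """Default-noise field with the standard cohort fractions."""
    cfg = SimulationConfig(**SMALL, rng_seed=13)
    return cfg, simulate_release_experiment(cfg)
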