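"""Shared fixtures: small simulated cells reused across test modules."""

from __future__ import annotations

import pytest

from kinetoquant.simulate import SimulationConfig, simulate_cell


def small_config(**overrides) -> SimulationConfig:
    """A compact metaphase cell (6 pairs) that simulates in ~10 ms."""
    defaults = dict(
        n_pairs=6,
        plate_radius_um=1.6,
        shape_vox=(16, 48, 32),
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def noisefree_config(**overrides) -> SimulationConfig:
    """Small cell with all noise sources off and zero background."""
    defaults = dict(
        poisson_noise=False,
        read_noise_sd=0.0,
        background_level=0.0,
        crest_amp_cv=0.0,
        sac_amp_cv=0.0,
    )
    defaults.update(overrides)
    return small_config(**defaults)


@pytest.fixture(scope="session")
def small_cell():
    """Default-noise small cell (stack, truth)."""
    return simulate_cell(small_config())


@pytest.fixture(scope="session")
def noisefree_cell():
    """Noise-free small cell with constant background 20 (stack, truth)."""
    return simulate_cell(noisefree_config(background_level=20.0))


@pytest.fixture(scope="session")
def default_cell():
    """One full-size default-geometry cell (40 pairs, default noise)."""
    return simulate_cell(SimulationConfig(seed=11))
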