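import numpy as np
import pytest

from cotrack.simulate import SimulationConfig, simulate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def quiet_config(**overrides) -> SimulationConfig:
    """A small, noise-free configuration for deterministic fixtures."""
    base = dict(
        kon_um2_per_molecule_s=0.0,
        koff_per_s=1.0,
        loc_sigma_um=0.0,
        registration_residual_um=0.0,
        dropout_prob=0.0,
        confinement_area_fraction=0.0,
        n_frames=100,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def binding_field():
    """One interacting field at paper-like densities, shared across tests."""
    cfg = SimulationConfig(
        kon_um2_per_molecule_s=0.4,
        koff_per_s=0.64,
        reaction_radius_um=0.25,
        binding_hazard=0.35,
        seed=42,
    )
    a, b, truth = simulate_field(cfg)
    return cfg, a, b, truth
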