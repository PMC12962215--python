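import pytest

from phyllotaxis3d import (
    ImperfectionModel,
    TrajectoryConfig,
    build_spoke_set,
    salt_water_ball,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def small_ball():
    """Soft-edged homogeneous ball sized for matrix-32 reconstructions."""
    return salt_water_ball(radius=8.0)


@pytest.fixture(scope="session")
def small_p2p_spokes():
    cfg = TrajectoryConfig(n_spokes=600, n_interleaves=10,
                           design="pole_to_pole", samples_per_spoke=49)
    return build_spoke_set(cfg)


@pytest.fixture(scope="session")
def odd_phase_model():
    """Direction-odd zeroth-order phase of 1 rad along z."""
    return ImperfectionModel(phase_coeffs=(0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def clean_small_kspace(small_ball, small_p2p_spokes):
    return simulate_acquisition(small_ball, small_p2p_spokes)


@pytest.fixture(scope="session")
def corrupted_small_kspace(small_ball, small_p2p_spokes, odd_phase_model):
    return simulate_acquisition(small_ball, small_p2p_spokes, odd_phase_model)
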