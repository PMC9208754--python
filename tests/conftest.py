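import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass


@pytest.fixture(scope="session")
def small_wrinkle_params():
    from wrinklekit.synthetic import WrinkleSimParams

    return WrinkleSimParams(
        shape=(128, 128),
        stage1_frames=14,
        stage2_frames=10,
        stage3_frames=6,
        nucleation_rate=0.7,
    )


@pytest.fixture(scope="session")
def small_wrinkle_data(small_wrinkle_params):
    from wrinklekit.synthetic import generate_wrinkle_timelapse

    return generate_wrinkle_timelapse(small_wrinkle_params, seed=1)


@pytest.fixture(scope="session")
def brownian_movie():
    """Small pure-diffuser movie with known diffusivity."""
    from wrinklekit.synthetic import SwimmerTruth, generate_swimmer_movie

    truth = SwimmerTruth(alpha=0.0, d_diff_um2_s=0.5, v_mean_um_s=25.0, n_particles=200)
    return generate_swimmer_movie(
        truth, fps=50.0, frames=400, shape=(128, 128), seed=7
    )
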