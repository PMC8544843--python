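import numpy as np
import pytest

from fallkin import CameraModel, FallParams, make_batch, simulate_fall


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fall_trial():
    """One default perturbation-based forward fall."""
    return simulate_fall(FallParams(trial_id="fwd_pert", seed=11))


@pytest.fixture(scope="session")
def planar_fall():
    """Noise-isolating fall: no out-of-plane motion, markers in the grid
    plane — the configuration for pipeline-error upper bounds."""
    return simulate_fall(
        FallParams(
            trial_id="planar",
            seed=5,
            out_of_plane_scale=0.0,
            marker_plane_offset=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_batch():
    """12 falls (2 per direction x initiation cell)."""
    return make_batch(n_per_cell=2, seed=3)


@pytest.fixture(scope="session")
def study_batch():
    """Full 36-fall study batch (6 per cell, as in the laboratory protocol)."""
    return make_batch(n_per_cell=6, seed=20)


@pytest.fixture
def camera_90():
    return CameraModel(angle_to_fall_plane=90.0)
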