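import numpy as np
import pytest

import tagtrack as tt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Fast 64x64 phantom configuration for unit tests."""
    return tt.PhantomConfig(
        image_size=(64, 64), inner_radius=10.0, outer_radius=22.0, frames=5
    )


@pytest.fixture(scope="session")
def default_study():
    """The 19-frame, 128x128 contraction+twist study (rendered once)."""
    return tt.generate_study(tt.PhantomConfig())


@pytest.fixture(scope="session")
def tracked_default_study(default_study):
    """Landmark trajectories tracked through the default study."""
    return tt.track_cycle(default_study.frames, default_study.landmarks)
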