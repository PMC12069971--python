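import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import retmap as rm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config():
    return rm.PipelineConfig()


@pytest.fixture(scope="session")
def default_grid(default_config):
    return rm.make_default_grid(default_config)


@pytest.fixture(scope="session")
def default_frame(default_config):
    return rm.EnFaceFrame.from_config(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """Two noiseless eyes: registration is exactly recoverable."""
    cfg = rm.PipelineConfig(n_eyes=2, seed=11, landmark_jitter_px=0.0)
    return rm.simulate_cohort(config=cfg)


@pytest.fixture(scope="session")
def cohort20():
    """One default 20-eye cohort (in-memory), shared across read-only tests."""
    return rm.simulate_cohort(n_eyes=20, seed=1)


@pytest.fixture(scope="session")
def pointwise20():
    """Fast-path analysis table for the same conditions."""
    return rm.simulate_pointwise(seed=1, n_eyes=20)


def child_seeds(root: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(root).spawn(n)]
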