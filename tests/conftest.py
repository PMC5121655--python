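import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# statsmodels emits convergence chatter on small mixed models; the fits
# themselves are checked by value below
warnings.filterwarnings("ignore", module="statsmodels")
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def default_cohort():
    from telodyn.synthetic import TrajectoryGenConfig, generate_trajectories

    return generate_trajectories(TrajectoryGenConfig(seed=42))


@pytest.fixture(scope="session")
def noisefree_cfg():
    from telodyn.synthetic import TrajectoryGenConfig

    return TrajectoryGenConfig(
        sd_subject=0.0, sd_plate=0.0, sd_resid=0.0, seed=1
    )


@pytest.fixture(scope="session")
def default_repro():
    from telodyn.synthetic import ReproGenConfig, generate_reproduction

    return generate_reproduction(ReproGenConfig(seed=42))


@pytest.fixture(scope="session")
def clean_plate():
    """Noise-free plate with perfect doubling on both assays."""
    from telodyn.synthetic import QpcrGenConfig, generate_qpcr_plate

    cfg = QpcrGenConfig(
        noise_sd_fluorescence=0.0,
        pipetting_sd_log=0.0,
        efficiency_telomere=2.0,
        efficiency_reference=2.0,
        seed=0,
    )
    return generate_qpcr_plate([("STD", 1.0), ("S1", 2.0)], cfg), cfg


def rng(seed=0):
    return np.random.default_rng(seed)
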