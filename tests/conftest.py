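import numpy as np
import pytest

from fiberpit import simulate as sim
from fiberpit.config import AnalysisConfig, SimConfig


@pytest.fixture(scope="session")
def photometry_config() -> SimConfig:
    """Imaging-variant conditioning design: 4 cues/type, 15-s probe."""
    return SimConfig.photometry_variant()


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Short sessions for fast pipeline tests (valid 2-min baselines)."""
    return SimConfig(
        n_subjects=3,
        n_conditioning_sessions=2,
        cs_per_type=2,
        cs_duration_s=60.0,
        iti_range_s=(120.0, 150.0),
        sample_rate_hz=10.0,
    )


@pytest.fixture(scope="session")
def default_session(photometry_config):
    """One fully simulated photometry conditioning session at defaults."""
    rng = np.random.default_rng(12345)
    contingency = sim.make_contingency(0)
    schedule = sim.generate_conditioning_session(
        photometry_config, contingency, 1, rng
    )
    log = sim.simulate_behavior(schedule, photometry_config, contingency, rng)
    rec = sim.simulate_photometry(schedule, log, photometry_config, rng)
    return schedule, log, rec, contingency
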