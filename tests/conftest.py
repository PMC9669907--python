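import numpy as np
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


@pytest.fixture(scope="session")
def default_study():
    """The full default synthetic study (10 teams x 16 trials), run once."""
    from herdlab.experiment import ExperimentConfig, run_experiment

    return run_experiment(ExperimentConfig(master_seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_activity(data, frame_rate=30.0):
    """Wrap a small 0/1 matrix as SpeakerActivity."""
    from herdlab.speech import SpeakerActivity

    data = np.asarray(data, dtype=np.int8)
    return SpeakerActivity(
        data, frame_rate=frame_rate, duration=len(data) / frame_rate
    )
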