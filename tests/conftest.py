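import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratsleep import synthetic, tree

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_study():
    """600-epoch default-recipe recording with ground truth (seed 42)."""
    recording, truth = synthetic.generate_study(n_epochs=600, seed=42)
    return recording, truth


@pytest.fixture(scope="session")
def clean_study_scored(clean_study):
    recording, truth = clean_study
    hypnogram, trace = tree.score_recording(recording)
    return recording, truth, hypnogram, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
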