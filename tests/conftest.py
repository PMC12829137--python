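import numpy as np
import pandas as pd
import pytest

from latentrl.decompose import fit_baseline
from latentrl.simulate import generate_synthetic_bird
from latentrl.trajectory import PitchTrajectory, split_baseline_feedback


@pytest.fixture(scope="session")
def small_feedback_bird():
    """Compact conditioning experiment (2 baseline + 3 feedback days)."""
    return generate_synthetic_bird(
        "feedback", seed=0, n_baseline_days=2, n_feedback_days=3,
        renditions_per_day=(300, 600),
    )


@pytest.fixture(scope="session")
def baseline_bird():
    """Free-singing bird (4 days, no feedback) with ground truth."""
    return generate_synthetic_bird("baseline_only", seed=1)


@pytest.fixture(scope="session")
def baseline_fit(baseline_bird):
    return fit_baseline(baseline_bird.traj)


@pytest.fixture(scope="session")
def split_small(small_feedback_bird):
    return split_baseline_feedback(small_feedback_bird.traj)


def make_traj(day, h, pitch, **cols):
    df = pd.DataFrame({"day": day, "h": h, "pitch_hz": pitch, **cols})
    return PitchTrajectory(df)


@pytest.fixture
def simple_traj():
    """Ten renditions spaced 0.1 s apart on one day."""
    sec = 30000.0 + 0.1 * np.arange(10)
    return make_traj(np.zeros(10, int), sec / 86400.0, np.full(10, 1000.0))
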