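import numpy as np
import pytest

from cortrack import workbench
from cortrack.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def fixture_study():
    """Miniature study: 3 subjects, 2 stimuli x 2 presentations, 4 channels."""
    return workbench.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def noisefree_study():
    """A single-subject noise-free study with 8 epochs for exact recovery."""
    cfg = SimConfig(
        n_subjects=1,
        n_stimuli=4,
        n_presentations=2,
        trial_duration=30.0,
        epoch_duration=30.0,
        n_channels=6,
        fs=64.0,
        snr_map={
            ("familiar", "low"): np.inf,
            ("unfamiliar", "low"): np.inf,
            ("familiar", "high"): np.inf,
            ("unfamiliar", "high"): np.inf,
        },
        seed=42,
    )
    return simulate_study(cfg)
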