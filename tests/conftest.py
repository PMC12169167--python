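import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from tendonmech.pipeline import RunConfig
from tendonmech.synthgen import StudySpec, TrialSpec, generate_study


@pytest.fixture(scope="session")
def clean_trial_spec() -> TrialSpec:
    """Noise-free trial: tracking and stiffness should be near-exact."""
    return TrialSpec(noise_force_sd=0.0, noise_image_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_trial_spec() -> TrialSpec:
    """Default speckle and sensor noise, fixed seed."""
    return TrialSpec(seed=11)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> Path:
    """A small synthetic study on disk, shared across pipeline tests."""
    root = tmp_path_factory.mktemp("study")
    spec = StudySpec(n_per_group=(2, 2), trials_per_session=2, seed=7)
    return generate_study(spec, root / "data")


@pytest.fixture()
def run_config(study_dir, tmp_path) -> RunConfig:
    return RunConfig(data_dir=str(study_dir), out_dir=str(tmp_path / "out"), seed=7)
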