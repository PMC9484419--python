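import numpy as np
import pytest

from uotcnr.config import StudyConfig


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def shallow_transport(study_config):
    """Paired A/B transport at the 1 cm reference depth (contrast 2), small run."""
    from uotcnr.transport import paired_transport

    phantom, scan_A, scan_B = study_config.scans(1.0, contrast=2.0)
    return paired_transport(phantom, scan_A, scan_B, 150_000, seed=11)


@pytest.fixture(scope="session")
def homogeneous_transport(study_config):
    """Contrast-1 run at the reference depth, used for calibration tests."""
    from uotcnr.transport import run_transport

    phantom, _, scan_B = study_config.scans(1.0, contrast=1.0)
    return run_transport(phantom, scan_B, 150_000, seed=5)
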