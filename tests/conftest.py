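import numpy as np
import pytest

from nirsgraph.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Four clean 30-min subjects (no artifacts, no saturation) with the
    generator's clean neural HbO kept for recovery checks."""
    spec = CohortSpec(n_subjects=4, duration=1800.0, seed=7,
                      artifact_rate=0.0, saturation_rate=0.0)
    scans, records, truth = generate_cohort(spec, keep_clean_hbo=True)
    return spec, scans, records, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Six 10-min subjects at the default artifact/saturation rates."""
    spec = CohortSpec(n_subjects=6, duration=600.0, seed=3)
    scans, records, truth = generate_cohort(spec)
    return spec, scans, records, truth


@pytest.fixture(scope="session")
def big_behavior_cohort():
    """116 subjects with short scans: used for behavior/ground-truth checks
    where the time series themselves are irrelevant."""
    spec = CohortSpec(n_subjects=116, duration=60.0, seed=21)
    scans, records, truth = generate_cohort(spec)
    return spec, scans, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
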