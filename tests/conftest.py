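import numpy as np
import pytest
from hypothesis import settings

from tetcad.synth import SyntheticCohortConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort shared across preprocessing/lead tests."""
    cfg = SyntheticCohortConfig(n_patients=6, prevalence=0.5, seed=0)
    patients, metadata = generate_cohort(cfg)
    return cfg, patients, metadata


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    from tetcad.synth import write_cohort

    cfg, patients, metadata = small_cohort
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(patients, metadata, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
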