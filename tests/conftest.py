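import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by detection/CPD/labeling tests."""
    from thermoshock.synthetic import CohortSpec, generate_cohort
    return generate_cohort(CohortSpec(n_patients=8, seed=7))


@pytest.fixture(scope="session")
def trained_models(small_cohort):
    """Abdomen+foot forests trained once on the shared cohort."""
    from thermoshock.pipeline import train_detectors
    return train_detectors(small_cohort, seed=7)


@pytest.fixture(scope="session")
def detection_experiment():
    """Detector validation at the documented problem size (shared with the
    acceptance checks): 12 training patients, 10 fresh evaluation patients
    (~50 images)."""
    from thermoshock.pipeline import run_detection_experiment
    return run_detection_experiment(seed=11, n_train_patients=12,
                                    n_eval_patients=10)


@pytest.fixture(scope="session")
def end_to_end():
    """Full simulate->train->detect->extract->label->fit->evaluate run at the
    study scale (51 patients), shared by evaluation and acceptance tests."""
    from thermoshock.pipeline import run_end_to_end
    return run_end_to_end(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
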