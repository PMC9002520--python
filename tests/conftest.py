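import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject default-error cohort shared by pipeline-level tests."""
    from sleepvalid.synthetic import CohortConfig, gen_cohort

    return gen_cohort(CohortConfig(seed=11, n_subjects=6))


@pytest.fixture(scope="session")
def clean_cohort():
    """An error-free cohort: the device reproduces the reference exactly."""
    from sleepvalid.synthetic import CohortConfig, DeviceConfig, gen_cohort

    device = DeviceConfig(
        hr_bias=0.0, br_bias=0.0,
        hr_noise_c0=0.0, br_noise_c0=0.0,
        hr_coverage=1.0, br_coverage=1.0,
        clock_offset_s=0.0,
        score_noise_sd=1e-9, score_sleep_p=0.99, score_wake_p=0.01,
    )
    cohort = CohortConfig(
        seed=5, n_subjects=5,
        bmi_noise_coef=0.0, sex_noise_coef=0.0,
        scorer_error_rate=0.0, psg_artifact_prob=0.0,
    )
    return gen_cohort(cohort, device_config=device)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
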