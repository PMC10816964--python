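import numpy as np
import pytest

from bamsa import RespondentRecord, calibrate_defaults, generate_cohort


def make_record(**overrides) -> RespondentRecord:
    """A valid respondent with unremarkable defaults; override per test."""
    base = dict(
        id="r1",
        sex="male",
        age_years=41.4,
        bmi_visit=27.3,
        neck_cm_visit=41.0,
        snoring_freq=1,
        apnea_freq=1,
        tiredness_freq=1,
        hypertension=False,
        ess_items=(1, 1, 2, 0, 1, 2, 1, 1),
        berlin_cat1_positive_items=0,
        berlin_cat2_positive_items=0,
        ahi=2.0,
    )
    base.update(overrides)
    return RespondentRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_params():
    return calibrate_defaults()


@pytest.fixture(scope="session")
def big_cohort():
    """One large default-parameter cohort shared across statistical tests."""
    return generate_cohort(calibrate_defaults(n=100_000, seed=1234))


@pytest.fixture(scope="session")
def big_cohort_arrays(big_cohort):
    return {
        "ahi": np.array([r.ahi for r in big_cohort]),
        "snoring": np.array([r.snoring_freq for r in big_cohort]),
        "apnea": np.array([r.apnea_freq for r in big_cohort]),
        "ess": np.array([sum(r.ess_items) for r in big_cohort]),
    }


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(calibrate_defaults(n=160, seed=5))
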